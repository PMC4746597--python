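"""Diversity statistics against independent literal-formula / brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from domscan.io_model import MISSING, GenomeLayout, make_metadata
from domscan import popgen_stats as ps

from conftest import make_matrix


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive)
# ---------------------------------------------------------------------------


def alleles_at_site(dosages: np.ndarray) -> list[int]:
    """Expand called dosages into individual alleles."""
    out = []
    for d in dosages:
        if d == MISSING:
            continue
        out += {0: [0, 0], 1: [0, 1], 2: [1, 1]}[int(d)]
    return out


def pi_site_bruteforce(dosages: np.ndarray) -> float:
    """Mean pairwise difference over all pairs of called alleles."""
    alleles = alleles_at_site(dosages)
    pairs = list(itertools.combinations(alleles, 2))
    if not pairs:
        return np.nan
    return float(np.mean([a != b for a, b in pairs]))


def tajimas_d_literal(dosage: np.ndarray) -> float:
    """Tajima (1989) D computed from first principles at equal allele counts."""
    n = 2 * dosage.shape[1]
    alt = dosage.sum(axis=1)
    seg = (alt > 0) & (alt < n)
    S = int(seg.sum())
    if S == 0:
        return np.nan
    k = 0.0
    for row in dosage[seg]:
        alleles = alleles_at_site(row)
        k += np.mean([a != b for a, b in itertools.combinations(alleles, 2)])
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (k - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def wc84_literal(d1: np.ndarray, d2: np.ndarray) -> float:
    """Weir & Cockerham 1984 theta-hat, ratio of sums, no missing data."""
    num = den = 0.0
    r = 2
    for s1, s2 in zip(d1, d2):
        n1, n2 = len(s1), len(s2)
        p1, p2 = s1.sum() / (2 * n1), s2.sum() / (2 * n2)
        h1, h2 = np.mean(s1 == 1), np.mean(s2 == 1)
        nbar = (n1 + n2) / 2
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2v = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2v - (pbar * (1 - pbar) - s2v * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2v * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
        if a + b + c != 0:
            num += a
            den += a + b + c
    return num / den if den else np.nan


def one_window_layout(length: int = 10_000) -> GenomeLayout:
    return GenomeLayout(chromosomes=[("chr1", length)])


# ---------------------------------------------------------------------------
# site stats
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "dosages, p, maf, missing",
    [
        ([0, 1, 2], 0.5, 0.5, 0.0),
        ([0, 0, MISSING], 0.0, 0.0, 1 / 3),
        ([2, 2, 2, 1], 7 / 8, 1 / 8, 0.0),
    ],
)
def test_site_stats_examples(dosages, p, maf, missing):
    m = make_matrix(np.array([dosages], dtype=np.int8))
    st = ps.site_stats(m)
    assert st["p"].iloc[0] == pytest.approx(p)
    assert st["maf"].iloc[0] == pytest.approx(maf)
    assert st["missing_frac"].iloc[0] == pytest.approx(missing)


def test_site_stats_empty_subset_rejected(two_pop_matrix):
    m, _ = two_pop_matrix
    with pytest.raises(ValueError):
        ps.site_stats(m, [])


# ---------------------------------------------------------------------------
# pi
# ---------------------------------------------------------------------------


class TestPi:
    def test_single_site_example(self):
        # dosages [0, 2] -> alleles 0,0,1,1: 4 of 6 pairs differ
        m = make_matrix(np.array([[0, 2]], dtype=np.int8), positions=[5_000])
        windows = ps.make_windows(one_window_layout(), 10_000)
        pi = ps.pi_windows(m, None, windows)
        assert pi[0] == pytest.approx((4 / 6) / 10_000)

    def test_monomorphic_window_is_zero(self):
        m = make_matrix(np.zeros((3, 4), dtype=np.int8), positions=[10, 20, 30])
        windows = ps.make_windows(one_window_layout(), 10_000)
        assert ps.pi_windows(m, None, windows)[0] == 0.0

    def test_matches_bruteforce_on_random_windows(self, rng):
        for _ in range(50):
            n_sites = int(rng.integers(1, 8))
            dosage = rng.choice(
                [0, 1, 2, MISSING], size=(n_sites, 6), p=[0.3, 0.25, 0.3, 0.15]
            ).astype(np.int8)
            m = make_matrix(dosage, positions=sorted(rng.choice(9_999, n_sites, replace=False).tolist()))
            windows = ps.make_windows(one_window_layout(), 10_000)
            expected = np.nansum([pi_site_bruteforce(row) for row in dosage]) / 10_000
            got = ps.pi_windows(m, None, windows)[0]
            assert got == pytest.approx(expected, abs=1e-10)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------


class TestTajimasD:
    def test_no_segregating_sites_is_missing(self):
        m = make_matrix(np.full((2, 4), 2, dtype=np.int8), positions=[10, 20])
        windows = ps.make_windows(one_window_layout(), 10_000)
        assert np.isnan(ps.tajimas_d_windows(m, None, windows)[0])

    def test_three_singletons_matches_literal_formula(self):
        dosage = np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]], dtype=np.int8)
        m = make_matrix(dosage, positions=[10, 20, 30])
        windows = ps.make_windows(one_window_layout(), 10_000)
        got = ps.tajimas_d_windows(m, None, windows)[0]
        assert got == pytest.approx(tajimas_d_literal(dosage), abs=1e-10)

    def test_matches_literal_formula_on_random_inputs(self, rng):
        checked = 0
        while checked < 50:
            n_sites = int(rng.integers(1, 10))
            dosage = rng.integers(0, 3, size=(n_sites, 5)).astype(np.int8)
            expected = tajimas_d_literal(dosage)
            if np.isnan(expected):
                continue
            m = make_matrix(dosage, positions=sorted(rng.choice(9_999, n_sites, replace=False).tolist()))
            windows = ps.make_windows(one_window_layout(), 10_000)
            got = ps.tajimas_d_windows(m, None, windows)[0]
            assert got == pytest.approx(expected, abs=1e-10)
            checked += 1

    def test_neutral_equilibrium_mean_near_zero(self, equilibrium_sim):
        params, m, meta, _ = equilibrium_sim
        windows = ps.make_windows(params.layout(), 10_000)
        d = ps.tajimas_d_windows(m, None, windows)
        assert abs(np.nanmean(d)) < 0.3


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------


class TestFst:
    def _meta(self, n1: int, n2: int):
        return make_metadata(
            [f"S{i}" for i in range(n1 + n2)], ["wild"] * n1 + ["cultivated"] * n2
        )

    def test_fixed_difference_is_one(self):
        d = np.hstack([np.zeros((3, 20)), np.full((3, 20), 2)]).astype(np.int8)
        m = make_matrix(d, positions=[10, 20, 30])
        meta = self._meta(20, 20)
        windows = ps.make_windows(one_window_layout(), 10_000)
        assert ps.fst_windows(m, meta, windows)[0] == pytest.approx(1.0)

    def test_identical_populations_not_positive(self):
        block = np.array([[0, 0, 1, 1, 2, 2]] * 4, dtype=np.int8)
        d = np.hstack([block, block])
        m = make_matrix(d, positions=[10, 20, 30, 40])
        meta = self._meta(6, 6)
        windows = ps.make_windows(one_window_layout(), 10_000)
        assert ps.fst_windows(m, meta, windows)[0] <= 0.0

    def test_hand_example_matches_literal_formula(self):
        d1 = np.array([[0, 0, 1, 1]], dtype=np.int8)
        d2 = np.array([[1, 1, 2, 2]], dtype=np.int8)
        m = make_matrix(np.hstack([d1, d2]), positions=[10])
        meta = self._meta(4, 4)
        windows = ps.make_windows(one_window_layout(), 10_000)
        got = ps.fst_windows(m, meta, windows)[0]
        assert got == pytest.approx(wc84_literal(d1, d2), abs=1e-10)

    def test_matches_literal_formula_on_random_inputs(self, rng):
        checked = 0
        while checked < 50:
            n_sites = int(rng.integers(1, 8))
            d1 = rng.integers(0, 3, size=(n_sites, 6)).astype(np.int8)
            d2 = rng.integers(0, 3, size=(n_sites, 5)).astype(np.int8)
            expected = wc84_literal(d1, d2)
            if np.isnan(expected):
                continue
            m = make_matrix(np.hstack([d1, d2]), positions=sorted(rng.choice(9_999, n_sites, replace=False).tolist()))
            meta = self._meta(6, 5)
            windows = ps.make_windows(one_window_layout(), 10_000)
            got = ps.fst_windows(m, meta, windows)[0]
            assert got == pytest.approx(expected, abs=1e-10)
            checked += 1


# ---------------------------------------------------------------------------
# ROD, pairwise counts, partition
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "pi_w, pi_c, expected",
    [(0.2, 0.2, 0.0), (0.2, 0.0, 1.0), (0.1, 0.2, -1.0)],
)
def test_rod_examples(pi_w, pi_c, expected):
    assert ps.rod(pi_w, pi_c) == pytest.approx(expected)


def test_rod_undefined_when_wild_monomorphic():
    assert np.isnan(ps.rod(0.0, 0.1))


class TestPairwiseCounts:
    def test_identical_and_opposite(self):
        m = make_matrix(np.array([[0, 0], [1, 1], [2, 2]], dtype=np.int8))
        assert ps.mean_pairwise_snp_count(m) == 0.0
        m2 = make_matrix(np.array([[0, 2], [0, 2], [0, 2]], dtype=np.int8))
        assert ps.mean_pairwise_snp_count(m2) == 3.0

    def test_matches_bruteforce(self, rng):
        for _ in range(20):
            dosage = rng.choice([0, 1, 2, MISSING], size=(5, 4)).astype(np.int8)
            m = make_matrix(dosage)
            expected = []
            for i, j in itertools.combinations(range(4), 2):
                both = (dosage[:, i] != MISSING) & (dosage[:, j] != MISSING)
                expected.append(int((dosage[both, i] != dosage[both, j]).sum()))
            assert ps.mean_pairwise_snp_count(m) == pytest.approx(np.mean(expected))

    def test_requires_two_samples(self):
        m = make_matrix(np.zeros((2, 1), dtype=np.int8))
        with pytest.raises(ValueError):
            ps.mean_pairwise_snp_count(m)


class TestRodProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        pw=st.floats(min_value=1e-9, max_value=1.0),
        pc=st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(derandomize=True, max_examples=100)
    def test_rod_bounded_above_and_monotone(self, pw, pc):
        r = ps.rod(pw, pc)
        assert r <= 1.0
        # increasing cultivated diversity can only lower ROD
        assert ps.rod(pw, pc + 0.1) <= r + 1e-12


class TestSharedUniquePartition:
    def test_classes(self):
        # rows: shared poly, wild-only, cultivated-only, monomorphic
        d = np.array(
            [
                [0, 1, 0, 1],
                [0, 1, 0, 0],
                [0, 0, 0, 1],
                [2, 2, 2, 2],
            ],
            dtype=np.int8,
        )
        m = make_matrix(d)
        meta = make_metadata(m.samples, ["wild", "wild", "cultivated", "cultivated"])
        part = ps.shared_unique_partition(m, meta)
        assert part == {"shared": 1, "wild_only": 1, "cultivated_only": 1, "monomorphic": 1}

    def test_partition_sums_to_total(self, rng):
        for _ in range(10):
            d = rng.choice([0, 1, 2, MISSING], size=(10, 6)).astype(np.int8)
            m = make_matrix(d)
            meta = make_metadata(m.samples, ["wild"] * 3 + ["cultivated"] * 3)
            part = ps.shared_unique_partition(m, meta)
            assert sum(part.values()) == 10


# ---------------------------------------------------------------------------
# combined table
# ---------------------------------------------------------------------------


def test_window_stats_table_shape(two_pop_matrix):
    m, meta = two_pop_matrix
    layout = GenomeLayout(chromosomes=[("chr1", 300)])
    t = ps.window_stats(m, meta, layout, 100)
    assert len(t) == 3
    assert t["n_snps"].sum() == m.n_variants
    for col in ("pi_wild", "pi_cul", "fst", "rod", "tajd_wild", "tajd_cul"):
        assert col in t.columns
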