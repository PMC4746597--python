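"""Shared fixtures: tiny hand-built panels and one small simulated panel."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from domscan.io_model import GenomeLayout, GenotypeMatrix, make_metadata


def make_matrix(
    dosage: np.ndarray,
    positions: list[int] | None = None,
    chrom: str = "chr1",
    samples: list[str] | None = None,
) -> GenotypeMatrix:
    """GenotypeMatrix from a (variants x samples) dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_var, n_samp = dosage.shape
    if positions is None:
        positions = list(range(100, 100 + 10 * n_var, 10))
    if samples is None:
        samples = [f"S{i}" for i in range(n_samp)]
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "id": [f"{chrom}_{p}" for p in positions],
            "ref": "A",
            "alt": "C",
        }
    )
    m = GenotypeMatrix(variants=variants, samples=samples, dosage=dosage)
    m.validate()
    return m


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20160209)


@pytest.fixture(scope="session")
def two_pop_matrix() -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Hand-built 10-SNP, 8-sample two-population panel with missing data."""
    rng = np.random.default_rng(7)
    dosage = rng.integers(0, 3, size=(10, 8)).astype(np.int8)
    dosage[2, 1] = -1
    dosage[5, 6] = -1
    m = make_matrix(dosage)
    meta = make_metadata(
        m.samples, ["wild"] * 4 + ["cultivated"] * 4
    )
    return m, meta


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated two-population panel shared across tests.

    0.6 Mb over 2 chromosomes, N=200, with one planted sweep; small enough
    to simulate in a few seconds yet structured enough for PCA/GWAS tests.
    """
    from domscan.simulate import SimParams, simulate_two_pop

    params = SimParams(
        L=600_000,
        n_chrom=2,
        N_anc=200,
        N_wild=200,
        N_cul=200,
        T_split=100,
        bottleneck_size=20,
        bottleneck_duration=30,
        n_sample_wild=25,
        n_sample_cul=40,
        sweep_loci=(("chr1", 150_000, 0.1),),
        seed=42,
    )
    m, meta, truth = simulate_two_pop(params)
    return params, m, meta, truth


@pytest.fixture(scope="session")
def equilibrium_sim():
    """Single panmictic equilibrium sample (T_split = 0), ~2 Mb."""
    from domscan.simulate import SimParams, simulate_two_pop

    params = SimParams(
        L=2_000_000,
        n_chrom=2,
        N_anc=300,
        T_split=0,
        bottleneck_duration=0,
        n_sample_wild=30,
        n_sample_cul=30,
        n_qtl=0,
        seed=11,
    )
    m, meta, truth = simulate_two_pop(params)
    return params, m, meta, truth


@pytest.fixture()
def layout_975() -> GenomeLayout:
    """20 chromosomes totalling 975 Mb, like the soybean reference."""
    return GenomeLayout(chromosomes=[(f"Gm{i+1:02d}", 48_750_000) for i in range(20)])
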