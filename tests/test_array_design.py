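"""Array-design selection stages and design-summary arithmetic."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from domscan import array_design as ad
from domscan.io_model import MISSING, GenomeLayout, GeneSet
from conftest import make_matrix


class TestFilterCandidates:
    @pytest.mark.parametrize(
        "dosages, expected",
        [
            ([0, 0, 0, 0, 0, 0, 0, 0, 0, 1], False),  # maf 0.05 < 0.10
            ([0, 1, 1, 0, 1, 0, 1, MISSING, MISSING, MISSING], False),  # missing 0.3
            ([0, 1, 1, 0, 1, 0, 1, 0, 0, MISSING], True),  # maf .22, missing .1
        ],
    )
    def test_rules(self, dosages, expected):
        m = make_matrix(np.array([dosages], dtype=np.int8))
        assert ad.filter_candidates(m)[0] == expected


class TestFlankUnique:
    def _matrix_at(self, positions, chrom="chr1"):
        return make_matrix(
            np.zeros((len(positions), 2), dtype=np.int8), positions=positions, chrom=chrom
        )

    def test_duplicate_and_unique_contexts(self, rng):
        bases = np.array(list("ACGT"))
        core = "".join(rng.choice(bases, size=200))
        dup = "".join(rng.choice(bases, size=40))
        # duplicate block planted twice; SNP at centre of first copy
        seq = core + dup + core[::-1] + dup + "".join(rng.choice(bases, 60))
        ref = {"chr1": seq}
        m = self._matrix_at(sorted([len(core) + 20, 100, 5]))
        status = ad.flank_unique(m, ref)
        by_pos = dict(zip(m.variants["pos"], status.to_numpy()))
        assert by_pos[len(core) + 20] == "multi_hit"
        assert by_pos[100] == "unique"
        assert by_pos[5] == "non_evaluable"  # within 16 bp of the contig end

    def test_reverse_complement_duplicate_detected(self, rng):
        bases = np.array(list("ACGT"))
        block = "".join(rng.choice(bases, size=41))
        rc = block.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        filler = "".join(rng.choice(bases, size=120))
        seq = filler + block + filler[::-1] + rc + filler
        # naive scan oracle: count occurrences of the 33-mer on both strands
        m = self._matrix_at([len(filler) + 20])
        kmer = seq[len(filler) + 4 : len(filler) + 37]
        kmer_rc = kmer.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        n_occ = sum(
            seq[i : i + 33] in (kmer, kmer_rc) for i in range(len(seq) - 32)
        )
        status = ad.flank_unique(m, {"chr1": seq})
        assert n_occ >= 2
        assert status.iloc[0] == "multi_hit"


def matrix_with_r2_blocks(blocks: list[list[int]], n_samples: int = 20, seed: int = 0):
    """Matrix whose SNPs within a block are perfect copies (r²=1), blocks independent."""
    rng = np.random.default_rng(seed)
    rows = []
    positions = []
    pos = 100
    for block in blocks:
        base = rng.binomial(2, 0.5, size=n_samples).astype(np.int8)
        while np.std(base) == 0:
            base = rng.binomial(2, 0.5, size=n_samples).astype(np.int8)
        for _ in block:
            rows.append(base.copy())
            positions.append(pos)
            pos += 500
    return make_matrix(np.array(rows, dtype=np.int8), positions=positions)


class TestSelectTagSnps:
    def test_perfect_ld_block_needs_one_tag(self):
        m = matrix_with_r2_blocks([[1, 1, 1]])
        tags = ad.select_tag_snps(m, np.ones(3, dtype=bool))
        assert tags.sum() == 1

    def test_independent_snps_all_tags(self):
        m = matrix_with_r2_blocks([[1], [1], [1]], seed=3)
        tags = ad.select_tag_snps(m, np.ones(3, dtype=bool))
        assert tags.sum() == 3

    def test_six_snp_toy_equals_bruteforce_cover(self):
        # blocks of sizes 3, 2, 1: minimal cover = one per block
        m = matrix_with_r2_blocks([[1, 1, 1], [1, 1], [1]], seed=5)
        cand = np.ones(6, dtype=bool)
        tags = ad.select_tag_snps(m, cand)
        # brute force minimal set cover over the r2>=0.8 adjacency
        from domscan.linkage import pairwise_r2

        pairs = pairwise_r2(m, max_dist=10_000)
        adj = {i: {i} for i in range(6)}
        for r in pairs.itertuples():
            if r.r2 >= 0.8:
                adj[r.i].add(r.j)
                adj[r.j].add(r.i)
        best = None
        for k in range(1, 7):
            for combo in itertools.combinations(range(6), k):
                if set().union(*(adj[i] for i in combo)) == set(range(6)):
                    best = combo
                    break
            if best:
                break
        assert tags.sum() == len(best) == 3

    def test_every_candidate_tagged(self, rng):
        # random panel: verify the coverage property exhaustively
        d = rng.binomial(2, rng.uniform(0.2, 0.8, (15, 1)), size=(15, 30)).astype(np.int8)
        m = make_matrix(d, positions=list(range(0, 15_000, 1_000)))
        cand = ad.filter_candidates(m, maf_min=0.05)
        tags = ad.select_tag_snps(m, cand)
        from domscan.linkage import pairwise_r2

        pairs = pairwise_r2(m, max_dist=500_000)
        adj = {i: {i} for i in np.flatnonzero(cand)}
        for r in pairs.itertuples():
            if r.r2 >= 0.8 and cand[r.i] and cand[r.j]:
                adj[r.i].add(r.j)
                adj[r.j].add(r.i)
        tag_set = set(np.flatnonzero(tags))
        for i in np.flatnonzero(cand):
            assert adj[i] & tag_set, f"candidate {i} untagged"

    def test_greedy_within_2x_of_bruteforce(self, rng):
        from domscan.linkage import pairwise_r2

        for trial in range(8):
            n = int(rng.integers(4, 10))
            d = rng.binomial(2, 0.5, size=(n, 16)).astype(np.int8)
            keep = [i for i in range(n) if np.std(d[i]) > 0]
            d = d[keep]
            n = len(d)
            if n < 2:
                continue
            m = make_matrix(d, positions=list(range(0, n * 700, 700)))
            tags = ad.select_tag_snps(m, np.ones(n, dtype=bool))
            pairs = pairwise_r2(m, max_dist=10**6)
            adj = {i: {i} for i in range(n)}
            for r in pairs.itertuples():
                if r.r2 >= 0.8:
                    adj[r.i].add(r.j)
                    adj[r.j].add(r.i)
            best = n
            for k in range(1, n + 1):
                found = False
                for combo in itertools.combinations(range(n), k):
                    if set().union(*(adj[i] for i in combo)) == set(range(n)):
                        best, found = k, True
                        break
                if found:
                    break
            assert tags.sum() <= 2 * best


class TestFillWindows:
    def _setup(self):
        layout = GenomeLayout(chromosomes=[("chr1", 3_360)])
        genes = GeneSet(
            genes=pd.DataFrame(
                {"id": ["g"], "chrom": ["chr1"], "start": [0], "end": [300], "strand": ["+"]}
            )
        )
        return layout, genes

    def test_tile_with_tag_unchanged(self):
        layout, genes = self._setup()
        m = make_matrix(np.zeros((2, 2), dtype=np.int8), positions=[100, 800])
        tags = np.array([True, False])
        added = ad.fill_windows(m, tags, np.array([False, True]), genes, layout)
        assert not added.any()

    def test_genic_preferred(self):
        layout, genes = self._setup()
        # candidate at 100 is genic (gene spans [0,300)), 900 is intergenic
        m = make_matrix(np.zeros((2, 2), dtype=np.int8), positions=[100, 900])
        added = ad.fill_windows(m, np.zeros(2, bool), np.ones(2, bool), genes, layout)
        assert added.tolist() == [True, False]

    def test_nearest_to_center_wins(self):
        layout, genes = self._setup()
        # both intergenic at offsets 700 and 800; tile centre is 840
        m = make_matrix(np.zeros((2, 2), dtype=np.int8), positions=[700, 800])
        added = ad.fill_windows(m, np.zeros(2, bool), np.ones(2, bool), genes, layout)
        assert added.tolist() == [False, True]

    def test_never_adds_to_tile_with_selection(self, rng):
        layout = GenomeLayout(chromosomes=[("chr1", 33_600)])
        genes = GeneSet(genes=pd.DataFrame(columns=["id", "chrom", "start", "end", "strand"]))
        pos = sorted(rng.choice(33_000, size=30, replace=False).tolist())
        m = make_matrix(np.zeros((30, 2), dtype=np.int8), positions=pos)
        tags = rng.random(30) < 0.3
        added = ad.fill_windows(m, tags, ~tags, genes, layout)
        tile = m.variants["pos"].to_numpy() // 1_680
        for t in np.unique(tile):
            rows = tile == t
            if tags[rows].any():
                assert not added[rows].any()
            assert added[rows].sum() <= 1


class TestMergeVipAndSummary:
    def test_merge_vip(self, two_pop_matrix):
        m, _ = two_pop_matrix
        sel = m.variants[["id", "chrom", "pos"]].iloc[:2].copy()
        sel["reason"] = "tag"
        ids = m.variants["id"].tolist()
        out = ad.merge_vip(m, sel, [ids[0]])  # already selected
        assert len(out) == 2
        out = ad.merge_vip(m, sel, [ids[5], ids[6]])
        assert len(out) == 4
        assert (out["reason"] == "vip").sum() == 2
        with pytest.warns(UserWarning):
            out = ad.merge_vip(m, sel, ["nonexistent"])
        assert len(out) == 2

    def test_printed_spacing_arithmetic(self, layout_975):
        # 291,962 chromosome-mapped SNPs over 975 Mb -> ~3.3 kb
        assert ad.mean_spacing_bp(layout_975.total_bp, 291_962) == pytest.approx(
            3_339.6, abs=0.5
        )

    def test_summary_single_snp(self):
        layout = GenomeLayout(chromosomes=[("chr1", 10_000)])
        design = ad.ArrayDesign(
            table=pd.DataFrame(
                {"id": ["x"], "chrom": ["chr1"], "pos": [100], "reason": ["tag"]}
            )
        )
        s = ad.design_summary(design, layout)
        assert np.isnan(s["spacing_below_threshold_pct"])
        assert s["n_mapped"] == 1

    def test_summary_context_fractions_sum(self, rng):
        layout = GenomeLayout(
            chromosomes=[("chr1", 100_000)], pericentromeric=[("chr1", 30_000, 70_000)]
        )
        pos = sorted(rng.choice(100_000, size=50, replace=False).tolist())
        m = make_matrix(np.zeros((50, 2), dtype=np.int8), positions=pos)
        design = ad.ArrayDesign(
            table=m.variants[["id", "chrom", "pos"]].assign(reason="tag")
        )
        context = pd.Series(
            rng.choice(["CDS", "intron", "intergenic"], size=50),
            index=m.variants["id"],
        )
        s = ad.design_summary(design, layout, context=context)
        assert sum(s["context_pct"].values()) == pytest.approx(100.0, abs=0.1)
        assert s["pericentromeric_n"] + s["arm_n"] == 50
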