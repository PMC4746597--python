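"""Genotyping-array SNP selection pipeline and design-summary metrics.

Selection stages, in order:

1. :func:`filter_candidates` — keep SNPs with MAF >= 0.10 and missing
   fraction <= 0.2.
2. :func:`flank_unique` — the 33-mer centred on the SNP (16 bp of reference
   each side) must occur exactly once in the reference over both strands.
3. :func:`select_tag_snps` — greedy tag-SNP cover: repeatedly pick the
   candidate that tags (r^2 >= 0.8 within an LD window) the most untagged
   candidates.
4. :func:`fill_windows` — tile the genome with 1,680-bp windows; a window
   with candidates but no tag receives one SNP, genic preferred over
   intergenic, nearest the window centre.
5. :func:`merge_vip` — union a user list of must-have SNPs.

:func:`design_summary` recomputes the coverage metrics (mean spacing,
spacing fractions, context and pericentromeric fractions, genes covered)
from the selected id set and annotations.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .io_model import GeneSet, GenomeLayout, GenotypeMatrix
from .linkage import _pair_block
from .popgen_stats import site_stats

__all__ = [
    "ArrayDesign",
    "filter_candidates",
    "flank_unique",
    "select_tag_snps",
    "fill_windows",
    "merge_vip",
    "design_summary",
    "mean_spacing_bp",
    "run_design",
]


@dataclasses.dataclass
class ArrayDesign:
    """Selected SNP ids with the stage that introduced each."""

    table: pd.DataFrame  # id, chrom, pos, reason

    def __len__(self) -> int:
        return len(self.table)

    def ids(self) -> set[str]:
        return set(self.table["id"])


def filter_candidates(
    m: GenotypeMatrix, maf_min: float = 0.10, miss_max: float = 0.2
) -> np.ndarray:
    """Boolean candidate mask: MAF >= maf_min and missing fraction <= miss_max."""
    st = site_stats(m)
    maf = np.nan_to_num(st["maf"].to_numpy(), nan=0.0)
    return (maf >= maf_min) & (st["missing_frac"].to_numpy() <= miss_max)


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def flank_unique(
    m: GenotypeMatrix, reference: dict[str, str], flank: int = 16
) -> pd.Series:
    """Per-SNP flank-uniqueness status: unique / multi_hit / non_evaluable.

    The k-mer (k = 2*flank + 1) centred on the SNP position in the reference
    must occur exactly once across all reference sequences counting both
    strands; SNPs within *flank* bp of a sequence end are non-evaluable.
    """
    k = 2 * flank + 1
    counts: dict[str, int] = {}
    for seq in reference.values():
        for i in range(0, len(seq) - k + 1):
            kmer = seq[i : i + k]
            canon = min(kmer, _revcomp(kmer))
            counts[canon] = counts.get(canon, 0) + 1
    status = []
    for _, v in m.variants.iterrows():
        seq = reference.get(v["chrom"])
        pos = int(v["pos"])
        if seq is None or pos < flank or pos + flank >= len(seq):
            status.append("non_evaluable")
            continue
        kmer = seq[pos - flank : pos + flank + 1]
        canon = min(kmer, _revcomp(kmer))
        n = counts.get(canon, 0)
        # a palindromic k-mer is its own reverse complement; one genomic
        # occurrence then matches both strands but is still a single locus
        status.append("unique" if n == 1 else "multi_hit")
    return pd.Series(status, index=m.variants["id"].to_numpy(), name="flank_status")


def select_tag_snps(
    m: GenotypeMatrix,
    candidates: np.ndarray,
    r2_max: float = 0.8,
    window: int = 500_000,
    subset: list[str] | None = None,
) -> np.ndarray:
    """Greedy tag-SNP selection among candidate variant rows.

    Two candidates are in strong LD when r^2 >= *r2_max* and they lie within
    *window* bp on the same chromosome.  Repeatedly picks the candidate
    covering the most untagged candidates (itself included); ties broken by
    leftmost genome position.  Returns a boolean mask over variants marking
    tags; afterwards every candidate has r^2 >= r2_max with some tag (or is
    a tag).
    """
    candidates = np.asarray(candidates)
    if candidates.dtype == bool:
        cand_idx = np.flatnonzero(candidates)
    else:
        cand_idx = candidates
    d = m.dosage if subset is None else m.dosage[:, m.sample_indices(subset)]
    called = d != -1
    chroms = m.variants["chrom"].to_numpy()
    pos = m.variants["pos"].to_numpy()

    # adjacency over candidate list
    neighbors: dict[int, set[int]] = {int(i): {int(i)} for i in cand_idx}
    by_chrom: dict[str, np.ndarray] = {}
    for chrom in pd.unique(chroms[cand_idx]):
        sel = cand_idx[chroms[cand_idx] == chrom]
        sel = sel[np.argsort(pos[sel])]
        by_chrom[chrom] = sel
        p = pos[sel]
        for a in range(len(sel)):
            hi = np.searchsorted(p, p[a] + window, side="right")
            if hi <= a + 1:
                continue
            r2, valid = _pair_block(d, called, int(sel[a]), int(sel[a + 1]), int(sel[hi - 1]) + 1)
            # _pair_block spans a contiguous row range; restrict to candidates
            block_rows = np.arange(sel[a + 1], sel[hi - 1] + 1)
            in_cand = np.isin(block_rows, sel[a + 1 : hi])
            strong = in_cand & valid & (np.nan_to_num(r2, nan=0.0) >= r2_max)
            for j in block_rows[strong]:
                neighbors[int(sel[a])].add(int(j))
                neighbors[int(j)].add(int(sel[a]))

    untagged = set(int(i) for i in cand_idx)
    tags: list[int] = []
    # priority: coverage count desc, then (chrom, pos) asc
    while untagged:
        best = None
        best_key = None
        for i in neighbors:
            cov = len(neighbors[i] & untagged)
            if cov == 0:
                continue
            key = (-cov, chroms[i], pos[i])
            if best_key is None or key < best_key:
                best, best_key = i, key
        tags.append(best)
        untagged -= neighbors[best]
    mask = np.zeros(m.n_variants, dtype=bool)
    mask[tags] = True
    return mask


def fill_windows(
    m: GenotypeMatrix,
    tags: np.ndarray,
    candidates: np.ndarray,
    genes: GeneSet,
    layout: GenomeLayout,
    window: int = 1_680,
) -> np.ndarray:
    """Even-coverage fill: boolean mask of SNPs added to tag-free tiles.

    The genome is tiled with non-overlapping *window*-bp tiles.  A tile
    already containing a tag gets nothing; a tile with >= 1 candidate gets
    exactly one, preferring genic (inside any gene span) over intergenic and,
    within a class, the candidate nearest the tile centre (leftmost on ties).
    """
    tags = np.asarray(tags, dtype=bool)
    cand = np.asarray(candidates)
    if cand.dtype != bool:
        tmp = np.zeros(m.n_variants, dtype=bool)
        tmp[cand] = True
        cand = tmp
    pos = m.variants["pos"].to_numpy()
    chroms = m.variants["chrom"].to_numpy()
    genic = classify_genic(m, genes)

    added = np.zeros(m.n_variants, dtype=bool)
    for chrom, _length in layout.chromosomes:
        sel = np.flatnonzero(chroms == chrom)
        if sel.size == 0:
            continue
        p = pos[sel]
        tile = p // window
        for t in np.unique(tile):
            rows = sel[tile == t]
            if tags[rows].any():
                continue
            crows = rows[cand[rows]]
            if crows.size == 0:
                continue
            center = t * window + window / 2.0
            grows = crows[genic[crows]]
            pool = grows if grows.size else crows
            dist = np.abs(pos[pool] - center)
            added[pool[np.lexsort((pos[pool], dist))[0]]] = True
    return added


def merge_vip(
    m: GenotypeMatrix, selection: pd.DataFrame, vip_ids: list[str]
) -> pd.DataFrame:
    """Union VIP SNPs into a selection table (id, chrom, pos, reason)."""
    known = {v: i for i, v in enumerate(m.variants["id"])}
    have = set(selection["id"])
    rows = []
    for vid in vip_ids:
        if vid not in known:
            warnings.warn(f"unknown VIP SNP {vid} skipped")
            continue
        if vid in have:
            continue
        i = known[vid]
        rows.append((vid, m.variants.at[i, "chrom"], m.variants.at[i, "pos"], "vip"))
        have.add(vid)
    if rows:
        extra = pd.DataFrame(rows, columns=["id", "chrom", "pos", "reason"])
        selection = pd.concat([selection, extra], ignore_index=True)
    return selection.sort_values(["chrom", "pos"]).reset_index(drop=True)


def mean_spacing_bp(total_bp: int, n_snps: int) -> float:
    """Average SNP spacing as genome length over chromosome-mapped SNP count."""
    if n_snps <= 0:
        raise ValueError("need at least one SNP")
    return total_bp / n_snps


def design_summary(
    design: ArrayDesign,
    layout: GenomeLayout,
    genes: GeneSet | None = None,
    context: pd.Series | None = None,
    spacing_threshold: int = 9_000,
) -> dict:
    """Coverage metrics recomputable from the selected id set + annotations.

    ``mean_spacing_bp`` is total chromosome length over mapped SNP count;
    ``spacing_below_threshold_pct`` is over consecutive same-chromosome gaps;
    context fractions (if *context* per-id labels given) sum to 100%.
    """
    t = design.table.sort_values(["chrom", "pos"])
    known = set(layout.lengths())
    mapped = t[t["chrom"].isin(known)]
    n = len(mapped)
    out: dict = {"n_selected": len(t), "n_mapped": n}
    out["per_chromosome"] = mapped.groupby("chrom").size().to_dict()
    out["mean_spacing_bp"] = mean_spacing_bp(layout.total_bp, n) if n else np.nan
    gaps = []
    for _chrom, grp in mapped.groupby("chrom"):
        p = grp["pos"].to_numpy()
        if len(p) > 1:
            gaps.append(np.diff(p))
    if gaps:
        gaps = np.concatenate(gaps)
        out["spacing_below_threshold_pct"] = round(
            100.0 * float((gaps < spacing_threshold).mean()), 2
        )
    else:
        out["spacing_below_threshold_pct"] = np.nan
    if context is not None:
        sub = context.loc[t["id"]]
        counts = sub.value_counts().to_dict()
        total = len(sub)
        out["context_counts"] = counts
        out["context_pct"] = {k: round(100.0 * v / total, 2) for k, v in counts.items()}
        out["genic_pct"] = round(
            100.0 * float((sub != "intergenic").mean()), 2
        )
    peri_n = 0
    if layout.pericentromeric:
        for _, row in mapped.iterrows():
            for chrom, s, e in layout.pericentromeric:
                if row["chrom"] == chrom and s <= row["pos"] < e:
                    peri_n += 1
                    break
        out["pericentromeric_n"] = peri_n
        out["arm_n"] = n - peri_n
        if n:
            out["pericentromeric_pct"] = round(100.0 * peri_n / n, 2)
            out["arm_pct"] = round(100.0 * (n - peri_n) / n, 2)
    if genes is not None:
        g = genes.genes
        covered = set()
        for chrom, grp in mapped.groupby("chrom"):
            gg = g[g["chrom"] == chrom]
            p = np.sort(grp["pos"].to_numpy())
            for _, row in gg.iterrows():
                lo = np.searchsorted(p, row["start"])
                if lo < len(p) and p[lo] < row["end"]:
                    covered.add(row["id"])
        out["genes_covered_n"] = len(covered)
        if len(g):
            out["genes_covered_pct"] = round(100.0 * len(covered) / len(g), 2)
    return out


def run_design(
    m: GenotypeMatrix,
    reference: dict[str, str],
    genes: GeneSet,
    layout: GenomeLayout,
    vip_ids: list[str] | None = None,
    maf_min: float = 0.10,
    miss_max: float = 0.2,
    r2_max: float = 0.8,
    ld_window: int = 500_000,
    fill_window: int = 1_680,
) -> ArrayDesign:
    """Full selection pipeline: filter -> flank -> tags -> fill -> VIP."""
    cand = filter_candidates(m, maf_min=maf_min, miss_max=miss_max)
    status = flank_unique(m, reference)
    cand &= (status == "unique").to_numpy()
    tags = select_tag_snps(m, cand, r2_max=r2_max, window=ld_window)
    fills = fill_windows(m, tags, cand & ~tags, genes, layout, window=fill_window)
    v = m.variants
    genic_fill = fills & (classify_genic(m, genes))
    reason = np.where(
        tags, "tag", np.where(genic_fill, "window-fill-genic", "window-fill-intergenic")
    )
    sel = tags | fills
    table = v.loc[sel, ["id", "chrom", "pos"]].copy()
    table["reason"] = reason[sel]
    table = merge_vip(m, table.reset_index(drop=True), vip_ids or [])
    return ArrayDesign(table=table)


def classify_genic(m: GenotypeMatrix, genes: GeneSet) -> np.ndarray:
    """Boolean: SNP lies inside any gene span."""
    pos = m.variants["pos"].to_numpy()
    chroms = m.variants["chrom"].to_numpy()
    genic = np.zeros(m.n_variants, dtype=bool)
    for chrom, grp in genes.genes.groupby("chrom"):
        sel = chroms == chrom
        if not sel.any():
            continue
        srt = grp.sort_values("start")
        starts = srt["start"].to_numpy()
        run_end = np.maximum.accumulate(srt["end"].to_numpy())
        j = np.searchsorted(starts, pos[sel], side="right") - 1
        ok = j >= 0
        inside = np.zeros(j.shape, dtype=bool)
        inside[ok] = pos[sel][ok] < run_end[j[ok]]
        genic[sel] = inside
    return genic
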