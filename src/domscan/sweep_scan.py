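"""Composite artificial-selection scan: ROD + F_ST empirical tails.

A 10-kb window is called a domestication-selection window when it lies in
the top tail of the pooled empirical distributions of BOTH statistics:
ROD = 1 - pi_cul/pi_wild and Weir-Cockerham F_ST.  With the default
q = 0.95 the threshold for each statistic is its k-th largest defined value,
k = floor((1-q) * n_defined), and a window is called iff it reaches both
thresholds (ties at a threshold are included).  Windows where ROD is
undefined (pi_wild = 0) carry no domestication signal and are excluded from
the pools and from calling.  Adjacent called windows are merged into sweep
regions and annotated with the genes they overlap.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io_model import GeneSet, GenomeLayout, GenotypeMatrix
from .popgen_stats import window_stats

__all__ = [
    "SweepRegion",
    "scan_windows",
    "call_selection_windows",
    "merge_called",
    "annotate_regions",
    "genome_fraction",
]


@dataclasses.dataclass
class SweepRegion:
    """A maximal run of adjacent called windows (0-based half-open)."""

    chrom: str
    start: int
    end: int
    n_windows: int
    mean_rod: float
    mean_fst: float
    genes: list[str] = dataclasses.field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


def scan_windows(
    m: GenotypeMatrix, meta: pd.DataFrame, layout: GenomeLayout, window: int = 10_000
) -> pd.DataFrame:
    """Window-statistics table at sweep-scan resolution (default 10 kb)."""
    return window_stats(m, meta, layout, window)


def call_selection_windows(table: pd.DataFrame, q: float = 0.95) -> pd.DataFrame:
    """Flag windows in the upper tail of both the ROD and F_ST pools.

    Returns *table* with added boolean column ``called`` plus attrs
    ``rod_threshold`` / ``fst_threshold``.  Requires >= 20 windows with both
    statistics defined.
    """
    if not (0 <= q < 1):
        raise ValueError("q must be in [0, 1)")
    rod = table["rod"].to_numpy(float)
    fst = table["fst"].to_numpy(float)
    defined = ~np.isnan(rod) & ~np.isnan(fst)
    n = int(defined.sum())
    if n < 20:
        raise ValueError(f"only {n} windows with both ROD and F_ST defined (< 20)")

    def tail_threshold(x: np.ndarray) -> float:
        xs = np.sort(x[defined])
        k = int(np.floor((1.0 - q) * n))
        if k <= 0:
            k = 1
        if q == 0:
            return float(xs[0])
        return float(xs[n - k])

    thr_rod = tail_threshold(rod)
    thr_fst = tail_threshold(fst)
    out = table.copy()
    out["called"] = defined & (rod >= thr_rod) & (fst >= thr_fst)
    out.attrs["rod_threshold"] = thr_rod
    out.attrs["fst_threshold"] = thr_fst
    return out


def merge_called(table: pd.DataFrame) -> list[SweepRegion]:
    """Merge book-ended called windows per chromosome into SweepRegions."""
    called = table[table["called"]].sort_values(["chrom", "start"])
    regions: list[SweepRegion] = []
    run: list[pd.Series] = []

    def flush() -> None:
        if not run:
            return
        regions.append(
            SweepRegion(
                chrom=run[0]["chrom"],
                start=int(run[0]["start"]),
                end=int(run[-1]["end"]),
                n_windows=len(run),
                mean_rod=float(np.mean([w["rod"] for w in run])),
                mean_fst=float(np.mean([w["fst"] for w in run])),
            )
        )

    for _, w in called.iterrows():
        if run and (w["chrom"] != run[-1]["chrom"] or w["start"] != run[-1]["end"]):
            flush()
            run = []
        run.append(w)
    flush()
    return regions


def annotate_regions(regions: list[SweepRegion], genes: GeneSet) -> list[SweepRegion]:
    """Attach ids of genes overlapping each region by >= 1 bp (in place)."""
    g = genes.genes
    for r in regions:
        on = g[(g["chrom"] == r.chrom) & (g["start"] < r.end) & (g["end"] > r.start)]
        r.genes = on["id"].tolist()
    return regions


def region_gene_ids(regions: list[SweepRegion]) -> set[str]:
    """Distinct genes over all regions (a gene spanning two regions counts once)."""
    out: set[str] = set()
    for r in regions:
        out.update(r.genes)
    return out


def genome_fraction(regions: list[SweepRegion], layout: GenomeLayout) -> float:
    """Percent of the genome covered by the regions, to 2 decimals."""
    total = layout.total_bp
    if total <= 0:
        raise ValueError("layout total length must be positive")
    bp = sum(r.length for r in regions)
    return round(100.0 * bp / total, 2)
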