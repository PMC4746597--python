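"""Pairwise r², LD-decay curve, and half-decay distance.

r² is the squared Pearson correlation of dosage vectors over the samples
non-missing at both sites (the composite/Rogers-Huff measure, suitable for
unphased genotypes).  Pairs never cross chromosomes.  The decay curve bins
pairs by physical distance; its "maximum" is defined as the first populated
bin's mean, since r² is maximal at short range under decay, and the
half-decay distance is where the binned mean first falls to half of that,
with linear interpolation between the straddling bins.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .io_model import MISSING, GenotypeMatrix

__all__ = ["LDDecayCurve", "pairwise_r2", "ld_decay", "ld_decay_curve", "half_decay_distance"]


@dataclasses.dataclass
class LDDecayCurve:
    """Binned mean r² against distance; bins are contiguous from 0."""

    bin_width: int
    centers: np.ndarray  # bp, (k + 0.5) * bin_width
    mean_r2: np.ndarray  # NaN for empty bins
    counts: np.ndarray

    @property
    def max_r2(self) -> float:
        """Mean r² of the first populated bin."""
        pop = np.flatnonzero(self.counts > 0)
        if pop.size == 0:
            return np.nan
        return float(self.mean_r2[pop[0]])


def _pair_block(
    d: np.ndarray, called: np.ndarray, i: int, j0: int, j1: int
) -> tuple[np.ndarray, np.ndarray]:
    """r² of site *i* against sites [j0, j1) with pairwise deletion.

    Returns (r2, valid); invalid where a member is monomorphic among shared
    calls or fewer than 3 shared non-missing samples.
    """
    x = d[i].astype(np.float64)
    mx = called[i].astype(np.float64)
    X = d[j0:j1].astype(np.float64)
    M = called[j0:j1].astype(np.float64)
    xm = x * mx
    n = M @ mx
    sx = M @ xm
    sy = (X * M) @ mx
    sxy = (X * M) @ xm
    sxx = M @ (xm * x)
    syy = (X * X * M) @ mx
    with np.errstate(divide="ignore", invalid="ignore"):
        vx = n * sxx - sx**2
        vy = n * syy - sy**2
        r2 = (n * sxy - sx * sy) ** 2 / (vx * vy)
    valid = (n >= 3) & (vx > 0) & (vy > 0)
    return np.where(valid, r2, np.nan), valid


def pairwise_r2(
    m: GenotypeMatrix, subset: list[str] | None = None, max_dist: int = 1_000_000
) -> pd.DataFrame:
    """All same-chromosome site pairs within *max_dist* bp.

    Returns a DataFrame with columns chrom, i, j (variant row indices),
    dist and r2.  Pairs with a monomorphic member or < 3 shared calls are
    skipped.
    """
    d = m.dosage if subset is None else m.dosage[:, m.sample_indices(subset)]
    called = d != MISSING
    chroms = m.variants["chrom"].to_numpy()
    pos = m.variants["pos"].to_numpy()
    rows = []
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        p = pos[sel]
        for a, i in enumerate(sel):
            hi = np.searchsorted(p, p[a] + max_dist, side="right")
            if hi <= a + 1:
                continue
            r2, valid = _pair_block(d, called, i, sel[a + 1], sel[hi - 1] + 1)
            js = sel[a + 1 : hi]
            ok = valid
            for j, dist, r in zip(js[ok], (p[a + 1 : hi] - p[a])[ok], r2[ok]):
                rows.append((chrom, i, j, int(dist), float(r)))
    return pd.DataFrame(rows, columns=["chrom", "i", "j", "dist", "r2"])


def ld_decay_curve(pairs: pd.DataFrame, bin_width: int = 1_000) -> LDDecayCurve:
    """Bin a pair table (needs ``dist`` and ``r2`` columns) into a curve."""
    if len(pairs) == 0:
        raise ValueError("need at least one pair")
    dist = pairs["dist"].to_numpy()
    r2 = pairs["r2"].to_numpy()
    nbins = int(dist.max() // bin_width) + 1
    idx = (dist // bin_width).astype(np.int64)
    sums = np.bincount(idx, weights=r2, minlength=nbins)
    counts = np.bincount(idx, minlength=nbins)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (np.arange(nbins) + 0.5) * bin_width
    return LDDecayCurve(bin_width=bin_width, centers=centers, mean_r2=mean, counts=counts)


def ld_decay(
    m: GenotypeMatrix,
    subset: list[str] | None = None,
    max_dist: int = 1_000_000,
    bin_width: int = 1_000,
) -> LDDecayCurve:
    """LD-decay curve computed by streaming pair blocks into distance bins.

    Equivalent to ``ld_decay_curve(pairwise_r2(...))`` without materialising
    the pair table.
    """
    d = m.dosage if subset is None else m.dosage[:, m.sample_indices(subset)]
    called = d != MISSING
    chroms = m.variants["chrom"].to_numpy()
    pos = m.variants["pos"].to_numpy()
    nbins = max(int(max_dist // bin_width), 1)
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=np.int64)
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        p = pos[sel]
        for a, i in enumerate(sel):
            hi = np.searchsorted(p, p[a] + max_dist, side="right")
            if hi <= a + 1:
                continue
            r2, valid = _pair_block(d, called, i, sel[a + 1], sel[hi - 1] + 1)
            dist = p[a + 1 : hi] - p[a]
            idx = np.minimum(dist // bin_width, nbins - 1).astype(np.int64)
            sums += np.bincount(idx[valid], weights=r2[valid], minlength=nbins)
            counts += np.bincount(idx[valid], minlength=nbins)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (np.arange(nbins) + 0.5) * bin_width
    return LDDecayCurve(bin_width=bin_width, centers=centers, mean_r2=mean, counts=counts)


def half_decay_distance(curve: LDDecayCurve) -> float | None:
    """Distance at which the binned mean r² falls to half of the curve max.

    Linear interpolation between the populated bins straddling the half
    level; ``None`` (with a warning) if the curve never falls that far.
    """
    pop = np.flatnonzero(curve.counts > 0)
    if pop.size == 0:
        raise ValueError("curve has no populated bin")
    half = curve.mean_r2[pop[0]] / 2.0
    prev = pop[0]
    for k in pop[1:]:
        if curve.mean_r2[k] <= half:
            m0, m1 = curve.mean_r2[prev], curve.mean_r2[k]
            c0, c1 = curve.centers[prev], curve.centers[k]
            if m0 == m1:
                return float(c1)
            return float(c0 + (m0 - half) / (m0 - m1) * (c1 - c0))
        prev = k
    warnings.warn("LD curve never decays to half of its maximum")
    return None
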