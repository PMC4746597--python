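"""Per-site and per-window diversity statistics.

Implements allele frequencies/MAF, nucleotide diversity pi, Tajima's D,
Weir & Cockerham (1984) F_ST, the reduction-of-diversity statistic
ROD = 1 - pi_cultivated / pi_wild, mean pairwise SNP differences, and the
shared/unique polymorphism partition between two populations.

Window conventions: windows are non-overlapping tiles per chromosome
(0-based half-open); pi is normalised per bp by window length; windows with
no usable site get pi = 0 but undefined (NaN) Tajima's D / F_ST / ROD.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_model import MISSING, GenomeLayout, GenotypeMatrix, population_samples


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


def make_windows(layout: GenomeLayout, size: int) -> pd.DataFrame:
    """Tile every chromosome with non-overlapping windows of *size* bp.

    The final window of a chromosome is truncated at the chromosome end.
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    rows = []
    for chrom, length in layout.chromosomes:
        starts = np.arange(0, length, size)
        ends = np.minimum(starts + size, length)
        for s, e in zip(starts, ends):
            rows.append((chrom, int(s), int(e)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def assign_windows(m: GenotypeMatrix, windows: pd.DataFrame) -> np.ndarray:
    """Window row index for each variant (-1 when outside every window)."""
    idx = np.full(m.n_variants, -1, dtype=np.int64)
    vpos = m.variants["pos"].to_numpy()
    vchrom = m.variants["chrom"].to_numpy()
    for chrom, grp in windows.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        rows = grp.index.to_numpy()
        mask = vchrom == chrom
        if not mask.any():
            continue
        p = vpos[mask]
        j = np.searchsorted(starts, p, side="right") - 1
        ok = (j >= 0) & (p < ends[np.clip(j, 0, len(ends) - 1)])
        out = np.full(p.shape, -1, dtype=np.int64)
        out[ok] = rows[j[ok]]
        idx[mask] = out
    return idx


# ---------------------------------------------------------------------------
# per-site statistics
# ---------------------------------------------------------------------------


def site_stats(m: GenotypeMatrix, subset: list[str] | None = None) -> pd.DataFrame:
    """Per-SNP allele counts over *subset* (default: all samples).

    Returns columns ``alt_count`` (alt alleles among calls), ``called``
    (called alleles, i.e. 2 x called genotypes), ``p`` (alt frequency),
    ``maf`` and ``missing_frac``.  Sites with zero calls have NaN p/maf.
    """
    if subset is not None and len(subset) == 0:
        raise ValueError("sample subset is empty")
    d = m.dosage if subset is None else m.dosage[:, m.sample_indices(subset)]
    called_gt = (d != MISSING).sum(axis=1)
    called = 2 * called_gt
    alt = np.where(d == MISSING, 0, d).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(called > 0, alt / np.maximum(called, 1), np.nan)
    maf = np.minimum(p, 1.0 - p)
    missing_frac = 1.0 - called_gt / d.shape[1]
    return pd.DataFrame(
        {
            "alt_count": alt,
            "called": called,
            "p": p,
            "maf": maf,
            "missing_frac": missing_frac,
        }
    )


def _site_pi(alt: np.ndarray, called: np.ndarray) -> np.ndarray:
    """Unbiased per-site heterozygosity 2p(1-p) * c/(c-1), NaN when c < 2.

    Equals the mean pairwise allele difference over all C(c,2) pairs of
    called alleles at the site.
    """
    c = called.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = alt / c
        pi = 2.0 * p * (1.0 - p) * c / (c - 1.0)
    pi[c < 2] = np.nan
    return pi


def pi_windows(
    m: GenotypeMatrix, subset: list[str] | None, windows: pd.DataFrame
) -> np.ndarray:
    """Per-bp nucleotide diversity per window (0 for windows with no site)."""
    st = site_stats(m, subset)
    pi_site = _site_pi(st["alt_count"].to_numpy(float), st["called"].to_numpy(float))
    widx = assign_windows(m, windows)
    ok = (widx >= 0) & ~np.isnan(pi_site)
    sums = np.bincount(widx[ok], weights=pi_site[ok], minlength=len(windows))
    span = (windows["end"] - windows["start"]).to_numpy(float)
    return sums / span


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------


def tajima_constants(n: int) -> dict[str, float]:
    """Standard a1,a2,b1,b2,c1,c2,e1,e2 constants for allele count n >= 2."""
    if n < 2:
        raise ValueError("need at least 2 alleles")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(pi_sum: float, n_seg: int, n_alleles: int) -> float:
    """Tajima (1989) D from summed pairwise diversity, S and allele count."""
    if n_seg == 0 or n_alleles < 2:
        return np.nan
    k = tajima_constants(n_alleles)
    var = k["e1"] * n_seg + k["e2"] * n_seg * (n_seg - 1)
    if var <= 0:
        return np.nan
    return (pi_sum - n_seg / k["a1"]) / np.sqrt(var)


def tajimas_d_windows(
    m: GenotypeMatrix, subset: list[str] | None, windows: pd.DataFrame
) -> np.ndarray:
    """Tajima's D per window (NaN when the window has no segregating site).

    With missing data the allele count varies per site; the constants use the
    median called-allele count over the window's segregating sites.
    """
    st = site_stats(m, subset)
    alt = st["alt_count"].to_numpy(float)
    called = st["called"].to_numpy(float)
    pi_site = _site_pi(alt, called)
    seg = (called >= 2) & (alt > 0) & (alt < called)
    widx = assign_windows(m, windows)
    out = np.full(len(windows), np.nan)
    ok = (widx >= 0) & seg
    for w in np.unique(widx[ok]):
        sel = ok & (widx == w)
        n = int(round(float(np.median(called[sel]))))
        out[w] = tajimas_d(float(np.nansum(pi_site[sel])), int(sel.sum()), n)
    return out


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) F_ST
# ---------------------------------------------------------------------------


def _wc84_components(
    d1: np.ndarray, d2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site WC84 variance components (a, b, c) for two populations.

    d1, d2: dosage matrices (sites x samples). Returns (a, b, c, valid);
    sites where either population has < 1 called diploid, where nbar <= 1,
    or where a+b+c == 0 are flagged invalid.
    """
    r = 2.0
    n1 = (d1 != MISSING).sum(axis=1).astype(float)
    n2 = (d2 != MISSING).sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(d1 == MISSING, 0, d1).sum(axis=1) / (2.0 * np.maximum(n1, 1e-12))
        p2 = np.where(d2 == MISSING, 0, d2).sum(axis=1) / (2.0 * np.maximum(n2, 1e-12))
        h1 = (d1 == 1).sum(axis=1) / np.maximum(n1, 1e-12)
        h2 = (d2 == 1).sum(axis=1) / np.maximum(n2, 1e-12)
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
    valid = (n1 >= 1) & (n2 >= 1) & (nbar > 1) & (nc > 0)
    denom = a + b + c
    valid &= np.isfinite(denom) & (denom != 0)
    return a, b, c, valid


def fst_weir_cockerham(d1: np.ndarray, d2: np.ndarray) -> float:
    """Ratio-of-sums WC84 F_ST over all valid sites of two dosage matrices."""
    a, b, c, valid = _wc84_components(d1, d2)
    denom = (a + b + c)[valid].sum()
    if denom == 0 or not valid.any():
        return np.nan
    return float(a[valid].sum() / denom)


def fst_windows(
    m: GenotypeMatrix, meta: pd.DataFrame, windows: pd.DataFrame
) -> np.ndarray:
    """WC84 F_ST per window (ratio-of-sums weighting; NaN when undefined)."""
    d1 = m.dosage[:, m.sample_indices(population_samples(meta, "wild"))]
    d2 = m.dosage[:, m.sample_indices(population_samples(meta, "cultivated"))]
    a, b, c, valid = _wc84_components(d1, d2)
    widx = assign_windows(m, windows)
    ok = (widx >= 0) & valid
    num = np.bincount(widx[ok], weights=a[ok], minlength=len(windows))
    den = np.bincount(widx[ok], weights=(a + b + c)[ok], minlength=len(windows))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


# ---------------------------------------------------------------------------
# ROD, pairwise differences, shared/unique partition
# ---------------------------------------------------------------------------


def rod(pi_wild: np.ndarray | float, pi_cul: np.ndarray | float) -> np.ndarray | float:
    """Reduction of diversity ROD = 1 - pi_cul / pi_wild (NaN if pi_wild=0)."""
    pw = np.asarray(pi_wild, dtype=float)
    pc = np.asarray(pi_cul, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(pw > 0, 1.0 - pc / np.where(pw > 0, pw, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def mean_pairwise_snp_count(m: GenotypeMatrix, subset: list[str] | None = None) -> float:
    """Mean over sample pairs of the number of differing co-called sites."""
    d = m.dosage if subset is None else m.dosage[:, m.sample_indices(subset)]
    n = d.shape[1]
    if n < 2:
        raise ValueError("need at least 2 samples")
    called = (d != MISSING).astype(np.float64)
    cocalled = called.T @ called
    same = np.zeros((n, n))
    for val in (0, 1, 2):
        g = (d == val).astype(np.float64)
        same += g.T @ g
    diff = cocalled - same
    iu = np.triu_indices(n, k=1)
    return float(diff[iu].mean())


def shared_unique_partition(m: GenotypeMatrix, meta: pd.DataFrame) -> dict[str, int]:
    """Partition SNPs into shared / wild-only / cultivated-only / monomorphic.

    Polymorphism is tested within each population over called alleles
    (maf > 0).  The four counts sum to the number of SNPs.
    """
    out = {}
    poly = {}
    for pop in ("wild", "cultivated"):
        st = site_stats(m, population_samples(meta, pop))
        maf = st["maf"].to_numpy()
        poly[pop] = np.nan_to_num(maf, nan=0.0) > 0
    out["shared"] = int((poly["wild"] & poly["cultivated"]).sum())
    out["wild_only"] = int((poly["wild"] & ~poly["cultivated"]).sum())
    out["cultivated_only"] = int((~poly["wild"] & poly["cultivated"]).sum())
    out["monomorphic"] = int((~poly["wild"] & ~poly["cultivated"]).sum())
    return out


# ---------------------------------------------------------------------------
# combined window table
# ---------------------------------------------------------------------------


def window_stats(
    m: GenotypeMatrix,
    meta: pd.DataFrame,
    layout: GenomeLayout,
    size: int,
) -> pd.DataFrame:
    """Build the per-window statistics table at the given window size.

    Columns: chrom, start, end, n_snps, pi_wild, pi_cul, tajd_wild, tajd_cul,
    maf_wild, maf_cul, fst, rod.
    """
    windows = make_windows(layout, size)
    wild = population_samples(meta, "wild")
    cul = population_samples(meta, "cultivated")
    widx = assign_windows(m, windows)
    n_snps = np.bincount(widx[widx >= 0], minlength=len(windows))

    table = windows.copy()
    table["n_snps"] = n_snps
    table["pi_wild"] = pi_windows(m, wild, windows)
    table["pi_cul"] = pi_windows(m, cul, windows)
    table["tajd_wild"] = tajimas_d_windows(m, wild, windows)
    table["tajd_cul"] = tajimas_d_windows(m, cul, windows)
    for pop, col in ((wild, "maf_wild"), (cul, "maf_cul")):
        st = site_stats(m, pop)
        maf = st["maf"].to_numpy()
        ok = (widx >= 0) & ~np.isnan(maf)
        sums = np.bincount(widx[ok], weights=maf[ok], minlength=len(windows))
        counts = np.bincount(widx[ok], minlength=len(windows))
        with np.errstate(divide="ignore", invalid="ignore"):
            table[col] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    table["fst"] = fst_windows(m, meta, windows)
    table["rod"] = rod(table["pi_wild"].to_numpy(), table["pi_cul"].to_numpy())
    return table
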