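"""Seed-weight GWAS machinery.

* :func:`blup_phenotype` — two-way mixed model y = mu + environment (fixed)
  + genotype (random) + error, variance components by EM-REML on the mixed
  model equations; returns the genotype random-effect predictions (BLUPs,
  the across-environment breeding values used as the GWAS phenotype).
* :func:`vanraden_kinship` — K = ZZ' / (2 sum p(1-p)), Z = dosage - 2p.
* :func:`mlm_scan` — exact single-marker mixed linear model with a polygenic
  random effect u ~ (0, K sigma_g^2) and fixed covariates (intercept + top
  PCs); the variance ratio is estimated once on the null model by REML via
  the spectral decomposition of K and reused for every marker, then each
  marker gets a generalised-least-squares Wald test.
* :func:`significance_threshold` — the 1/n_markers rule.
* :func:`candidate_regions` — lead SNP +/- LD half-decay, merged, annotated.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .io_model import MISSING, GeneSet, GenomeLayout, GenotypeMatrix

__all__ = [
    "AssociationResult",
    "blup_phenotype",
    "vanraden_kinship",
    "mlm_scan",
    "significance_threshold",
    "candidate_regions",
]


# ---------------------------------------------------------------------------
# BLUP of multi-environment phenotypes
# ---------------------------------------------------------------------------


def blup_phenotype(
    pheno: pd.DataFrame,
    value_col: str = "hundred_seed_weight",
    max_iter: int = 500,
    tol: float = 1e-6,
) -> pd.Series:
    """Genotype BLUPs from a (sample, environment, replicate, value) table.

    Model: y = mu + env (fixed) + genotype (random, iid) + error.  Variance
    components are estimated by EM-REML iterated to relative tolerance *tol*;
    the returned Series holds each sample's random-effect prediction
    (centred breeding value).
    """
    samples = pd.unique(pheno["sample"])
    envs = pd.unique(pheno["environment"])
    if len(samples) < 2 or len(envs) < 2:
        raise ValueError("need >= 2 samples and >= 2 environments")
    y = pheno[value_col].to_numpy(float)
    n = len(y)
    s_idx = pd.Categorical(pheno["sample"], categories=samples).codes
    e_idx = pd.Categorical(pheno["environment"], categories=envs).codes
    p = len(envs)  # X: intercept absorbed into env one-hot (cell means for env)
    q = len(samples)
    X = np.zeros((n, p))
    X[np.arange(n), e_idx] = 1.0
    Z = np.zeros((n, q))
    Z[np.arange(n), s_idx] = 1.0

    xtx = X.T @ X
    xtz = X.T @ Z
    ztz = Z.T @ Z
    xty = X.T @ y
    zty = Z.T @ y
    rank_x = np.linalg.matrix_rank(xtx)

    scale = float(np.var(y)) or 1.0
    var_g = scale / 2
    var_e = scale / 2
    beta = np.zeros(p)
    g = np.zeros(q)
    for _ in range(max_iter):
        # the MME lose rank as var_e -> 0 (env and genotype designs share
        # the intercept), so the ratio is floored at a numerically safe value
        lam = max(var_e / var_g, 1e-8)
        C = np.block([[xtx, xtz], [xtz.T, ztz + lam * np.eye(q)]])
        rhs = np.concatenate([xty, zty])
        Cinv = linalg.inv(C)
        sol = Cinv @ rhs
        beta, g = sol[:p], sol[p:]
        resid = y - X @ beta - Z @ g
        new_e = float(y @ resid) / (n - rank_x)
        cgg_tr = float(np.trace(Cinv[p:, p:]))
        new_g = float(g @ g + new_e * cgg_tr) / q
        if new_e <= 1e-8 * scale:  # zero-residual boundary of the REML surface
            var_g, var_e = new_g, max(new_e, 0.0)
            break
        if (
            abs(new_g - var_g) <= tol * max(abs(var_g), 1e-10 * scale)
            and abs(new_e - var_e) <= tol * max(abs(var_e), 1e-10 * scale)
        ):
            var_g, var_e = new_g, new_e
            break
        var_g, var_e = max(new_g, 1e-12 * scale), max(new_e, 1e-12 * scale)
    else:
        raise RuntimeError(
            f"EM-REML did not converge in {max_iter} iterations "
            f"(var_g={var_g:.4g}, var_e={var_e:.4g})"
        )
    # final solve at converged components
    lam = max(var_e / var_g, 1e-8)
    C = np.block([[xtx, xtz], [xtz.T, ztz + lam * np.eye(q)]])
    sol = linalg.solve(C, np.concatenate([xty, zty]), assume_a="sym")
    out = pd.Series(sol[p:], index=list(samples), name="blup")
    out.attrs["var_g"] = var_g
    out.attrs["var_e"] = var_e
    return out


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------


def vanraden_kinship(m: GenotypeMatrix) -> np.ndarray:
    """VanRaden genomic relationship matrix over all samples.

    K = Z Z' / (2 sum_k p_k (1 - p_k)) with Z = dosage - 2p per SNP and
    missing dosages mean-imputed per SNP.  Monomorphic SNPs contribute
    nothing; all-monomorphic input is an error.
    """
    d = m.dosage.astype(np.float64)
    if m.n_samples < 2:
        raise ValueError("need at least 2 samples")
    miss = d == MISSING
    cnt = (~miss).sum(axis=1)
    alt = np.where(miss, 0, d).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = alt / (2.0 * np.maximum(cnt, 1))
    poly = (cnt > 0) & (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic SNP for kinship")
    d = d[poly]
    p = p[poly]
    miss = miss[poly]
    d[miss] = np.broadcast_to(2.0 * p[:, None], d.shape)[miss]
    z = d - 2.0 * p[:, None]
    denom = 2.0 * float((p * (1.0 - p)).sum())
    return (z.T @ z) / denom


# ---------------------------------------------------------------------------
# exact mixed linear model scan
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class AssociationResult:
    """Per-SNP scan results plus threshold and candidate regions."""

    table: pd.DataFrame  # id, chrom, pos, maf, beta, se, p
    threshold: float
    n_markers: int
    delta: float  # REML variance ratio sigma_e^2 / sigma_g^2 from the null
    regions: list[dict] = dataclasses.field(default_factory=list)

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["p"] < self.threshold]


def _reml_delta(y: np.ndarray, X: np.ndarray, evals: np.ndarray, U: np.ndarray) -> float:
    """REML-optimal delta = var_e/var_g for y = Xb + u + e, Var = vg(K + dI)."""
    n, p = X.shape
    yt = U.T @ y
    Xt = U.T @ X

    def neg_reml(log_d: float) -> float:
        d = np.exp(log_d)
        w = evals + d
        Xw = Xt / w[:, None]
        xtx = Xt.T @ Xw
        beta = linalg.solve(xtx, Xw.T @ yt, assume_a="pos")
        r = yt - Xt @ beta
        rss = float(r @ (r / w))
        sign, logdet_x = np.linalg.slogdet(xtx)
        return (
            (n - p) * np.log(rss)
            + float(np.log(w).sum())
            + logdet_x
        )

    res = optimize.minimize_scalar(neg_reml, bounds=(-12.0, 12.0), method="bounded")
    return float(np.exp(res.x))


def mlm_scan(
    m: GenotypeMatrix,
    y: pd.Series,
    K: np.ndarray | None = None,
    n_pcs: int = 5,
    maf_min: float = 0.05,
    call_rate_min: float = 0.9,
) -> AssociationResult:
    """Single-marker exact MLM scan of breeding values *y*.

    SNPs with MAF < *maf_min* or call rate < *call_rate_min* are excluded
    before testing; the significance threshold is 1/n over the tested
    markers.  Covariates are an intercept plus the top *n_pcs* principal
    components (computed from the filtered SNP set).  The variance ratio is
    estimated once on the null model and reused per marker; Wald p-values.
    """
    from .structure_phylo import pca_coords

    names = list(y.index)
    sub = m.subset_samples(names)
    d = sub.dosage.astype(np.float64)
    miss = d == MISSING
    cnt = (~miss).sum(axis=1)
    alt = np.where(miss, 0, d).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = alt / (2.0 * np.maximum(cnt, 1))
    maf = np.minimum(p, 1 - p)
    keep = (cnt / sub.n_samples >= call_rate_min) & (maf >= maf_min)
    sub = sub.take_variants(keep)
    d = d[keep]
    miss = miss[keep]
    p = p[keep]
    maf = maf[keep]
    n_markers = sub.n_variants
    if n_markers == 0:
        raise ValueError("no markers pass the MAF/call-rate filters")
    d[miss] = np.broadcast_to(2.0 * p[:, None], d.shape)[miss]

    if K is None:
        K = vanraden_kinship(sub)
    nsamp = len(names)
    yv = y.to_numpy(float)

    covar = [np.ones((nsamp, 1))]
    if n_pcs > 0:
        coords, _ = pca_coords(sub, k=n_pcs)
        covar.append(coords)
    X = np.hstack(covar)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular fixed-effect design (collinear covariates/PCs)")

    evals, U = linalg.eigh(K)
    evals = np.clip(evals, 0.0, None)
    delta = _reml_delta(yv, X, evals, U)

    w = evals + delta
    sw = np.sqrt(w)
    yt = (U.T @ yv) / sw
    Xt = (U.T @ X) / sw[:, None]
    Gt = (U.T @ d.T) / sw[:, None]  # samples x markers, whitened

    # Frisch-Waugh: residualise phenotype and markers on the covariates
    Q, _ = np.linalg.qr(Xt)
    ry = yt - Q @ (Q.T @ yt)
    RG = Gt - Q @ (Q.T @ Gt)
    gg = (RG * RG).sum(axis=0)
    gy = RG.T @ ry
    yy = float(ry @ ry)
    df = nsamp - X.shape[1] - 1
    if df <= 0:
        raise ValueError("not enough samples for the fixed-effect design")
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(gg > 1e-10, gy / np.maximum(gg, 1e-300), 0.0)
        rss = yy - beta * gy
        sigma2 = rss / df
        se = np.sqrt(np.maximum(sigma2, 0.0) / np.maximum(gg, 1e-300))
        tstat = np.where(gg > 1e-10, beta / np.maximum(se, 1e-300), 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    se = np.where(gg > 1e-10, se, np.nan)

    table = sub.variants[["id", "chrom", "pos"]].copy()
    table["maf"] = maf
    table["beta"] = beta
    table["se"] = se
    table["p"] = pvals
    return AssociationResult(
        table=table,
        threshold=significance_threshold(n_markers),
        n_markers=n_markers,
        delta=delta,
    )


def significance_threshold(n_markers: int) -> float:
    """The 1/n genome-wide threshold, to 3 significant figures."""
    if n_markers <= 0:
        raise ValueError("n_markers must be positive")
    return float(f"{1.0 / n_markers:.3g}")


# ---------------------------------------------------------------------------
# candidate regions
# ---------------------------------------------------------------------------


def candidate_regions(
    hits: pd.DataFrame,
    half_decay: int,
    genes: GeneSet | None = None,
    layout: GenomeLayout | None = None,
) -> list[dict]:
    """Lead-SNP regions: position +/- LD half-decay, merged when overlapping.

    *hits* needs columns chrom, pos, id, p.  Each merged region reports its
    most significant SNP as lead and the overlapping genes.
    """
    if len(hits) == 0:
        raise ValueError("no hits")
    lengths = layout.lengths() if layout is not None else {}
    rows = []
    for _, h in hits.iterrows():
        start = max(int(h["pos"]) - half_decay, 0)
        end = int(h["pos"]) + half_decay
        if h["chrom"] in lengths:
            end = min(end, lengths[h["chrom"]])
        rows.append(dict(chrom=h["chrom"], start=start, end=end, id=h["id"], pos=int(h["pos"]), p=float(h["p"])))
    rows.sort(key=lambda r: (r["chrom"], r["start"]))
    merged: list[dict] = []
    for r in rows:
        if merged and merged[-1]["chrom"] == r["chrom"] and r["start"] <= merged[-1]["end"]:
            cur = merged[-1]
            cur["end"] = max(cur["end"], r["end"])
            cur["snps"].append(r)
        else:
            merged.append(dict(chrom=r["chrom"], start=r["start"], end=r["end"], snps=[r]))
    out = []
    for reg in merged:
        lead = min(reg["snps"], key=lambda s: s["p"])
        entry = dict(
            chrom=reg["chrom"],
            start=reg["start"],
            end=reg["end"],
            lead_id=lead["id"],
            lead_pos=lead["pos"],
            lead_p=lead["p"],
            n_snps=len(reg["snps"]),
            genes=[],
        )
        if genes is not None:
            g = genes.genes
            on = g[(g["chrom"] == reg["chrom"]) & (g["start"] < reg["end"]) & (g["end"] > reg["start"])]
            entry["genes"] = on["id"].tolist()
        out.append(entry)
    return out
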