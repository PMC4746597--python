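"""Population structure: IBS distances, PCA coordinates, neighbor-joining.

The IBS distance between two samples scores each co-called site 1 for an
identical genotype, 0.5 for a one-allele match (het vs hom), 0 for opposite
homozygotes, i.e. score = 1 - |d_i - d_j| / 2, and takes one minus the mean
score.  PCA standardises each SNP by its allele frequency (Patterson
scaling) before the eigendecomposition.  The NJ tree is the Saitou-Nei
agglomeration; negative branch lengths are clamped to zero with the deficit
transferred to the sibling edge.
"""

from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix

from .io_model import MISSING, GenotypeMatrix

__all__ = ["ibs_distance", "pca_coords", "nj_tree"]


def ibs_distance(m: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise identity-by-state distance matrix over all samples."""
    d = m.dosage
    n = m.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples")
    called = (d != MISSING).astype(np.float64)
    x = np.where(d == MISSING, 0, d).astype(np.float64)
    cocalled = called.T @ called
    if (cocalled == 0).any():
        raise ValueError("a sample pair shares no called site; distance undefined")
    # sum |d_i - d_j| over co-called sites: (d_i-d_j)^2 - 2*[opposite homs]
    xm = x * called
    sq = (
        (xm * x).T @ called
        + called.T @ (xm * x)
        - 2.0 * xm.T @ xm
    )
    g0 = ((d == 0)).astype(np.float64)
    g2 = ((d == 2)).astype(np.float64)
    opp = g0.T @ g2 + g2.T @ g0
    absdiff = sq - 2.0 * opp
    dist = absdiff / (2.0 * cocalled)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # exact symmetry against float noise
    return DistanceMatrix(dist, ids=list(m.samples))


def pca_coords(m: GenotypeMatrix, k: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component coordinates of samples and variance fractions.

    Missing dosages are mean-imputed per SNP; each SNP is centred at 2p and
    scaled by sqrt(2p(1-p)).  Coordinates are deterministic up to sign; the
    sign is fixed so each component's largest-magnitude loading is positive.
    Returns (coords (n_samples x k), variance_fractions (k,)).
    """
    import warnings

    n = m.n_samples
    if n < k + 1:
        raise ValueError("need at least k+1 samples")
    d = m.dosage.astype(np.float64)
    miss = d == MISSING
    alt = np.where(miss, 0, d).sum(axis=1)
    cnt = (~miss).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = alt / (2.0 * np.maximum(cnt, 1))
    keep = (cnt > 0) & (p > 0) & (p < 1)
    d = d[keep]
    p = p[keep]
    miss = miss[keep]
    mean = 2.0 * p
    d[miss] = np.broadcast_to(mean[:, None], d.shape)[miss]
    z = (d - mean[:, None]) / np.sqrt(2.0 * p * (1.0 - p))[:, None]
    u, s, _vt = np.linalg.svd(z.T / np.sqrt(len(p)), full_matrices=False)
    rank = int((s > 1e-12 * s[0]).sum()) if s.size else 0
    if k > rank:
        warnings.warn(f"requested {k} components but rank is {rank}; reducing")
        k = rank
    coords = u[:, :k] * s[:k]
    sign = np.sign(coords[np.argmax(np.abs(coords), axis=0), np.arange(k)])
    sign[sign == 0] = 1.0
    coords = coords * sign
    var_frac = (s[:k] ** 2) / (s**2).sum()
    return coords, var_frac


def nj_tree(dm: DistanceMatrix) -> str:
    """Saitou-Nei neighbor-joining tree in Newick form (unrooted).

    Branch lengths follow the standard NJ formulas; a negative length is
    clamped to 0 and the deficit moved to the sibling edge so the pair's
    path length is preserved.
    """
    labels = list(dm.ids)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    D = np.asarray(dm.data, dtype=float).copy()
    nodes = [_escape(l) for l in labels]
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        k = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        a, b = np.unravel_index(np.argmin(q), q.shape)
        if a > b:
            a, b = b, a
        i, j = active[a], active[b]
        dij = D[i, j]
        li = 0.5 * dij + (r[a] - r[b]) / (2.0 * (k - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        new = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        # distances from the new node to every other active node
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.vstack([D, dnew])
        D = np.hstack([D, np.append(dnew, 0.0)[:, None]])
        nodes.append(new)
        active = [x for x in active if x not in (i, j)] + [len(nodes) - 1]

    i, j, l = active
    dij, dil, djl = D[i, j], D[i, l], D[j, l]
    li = 0.5 * (dij + dil - djl)
    lj = 0.5 * (dij + djl - dil)
    ll = 0.5 * (dil + djl - dij)
    li, lj, ll = max(li, 0.0), max(lj, 0.0), max(ll, 0.0)
    return f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g},{nodes[l]}:{ll:.10g});"


def _escape(label: str) -> str:
    if any(c in label for c in " (),:;'"):
        return "'" + label.replace("'", "''") + "'"
    return label
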