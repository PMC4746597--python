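"""Two-population domestication simulator with known sweeps and phenotypes.

The model is a wild progenitor population and a derived "cultivated"
population separated ``T_split`` generations ago.  The ancestral population
is drawn at neutral equilibrium from a seeded coalescent/DTWF sampler
(msprime), which gives the exact stationary distribution without a long
burn-in.  From the split onward, both daughter lineages evolve by an explicit
discrete-generation Wright-Fisher forward simulation (multinomial parent
sampling, uniform recombination, per-generation mutation), so that
domestication features are simple to impose on the cultivated lineage only:

* a bottleneck of ``bottleneck_size`` diploids for ``bottleneck_duration``
  generations immediately after the split, then recovery to ``N_cul``;
* positive selection (fitness ``(1+s)`` per beneficial allele copy) at each
  requested sweep locus: a de novo beneficial mutation injected into one
  founding cultivated haplotype, i.e. a classic hard sweep; an allele lost
  to drift triggers a bounded retry of the cultivated lineage.

Everything is deterministic given ``SimParams.seed``.

Multi-environment 100-seed-weight phenotypes are generated additively from
planted QTLs with environment main effects, genotype-by-environment noise
and replicate-level residuals, scaled so the genetic fraction of the
single-observation variance equals the requested heritability.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .io_model import (
    MISSING,
    GenomeLayout,
    GeneSet,
    GenotypeMatrix,
    make_metadata,
)

__all__ = [
    "SimParams",
    "SimTruth",
    "SweepLostError",
    "default_sweep_loci",
    "simulate_two_pop",
    "simulate_phenotypes",
    "random_reference",
    "tile_genes",
]


class SweepLostError(RuntimeError):
    """A beneficial allele was lost in every retry of the cultivated lineage."""


@dataclasses.dataclass
class SimParams:
    """Simulation parameters.

    Genome and rates are per-bp per-generation; sizes are diploid counts.
    Defaults are desk-scale placeholders chosen to produce clear
    domestication signatures (see docs/methods.md), not inferred soybean
    demography.
    """

    L: int = 5_000_000
    n_chrom: int = 5
    mu: float = 2.0e-7
    rho: float = 2.0e-7
    N_anc: int = 500
    N_wild: int = 500
    N_cul: int = 500
    T_split: int = 110
    bottleneck_size: int = 50
    bottleneck_duration: int = 50
    sweep_loci: tuple[tuple[str, int, float], ...] = ()
    n_qtl: int = 3
    qtl_effect_sd: float = 1.5
    n_sample_wild: int = 40
    n_sample_cul: int = 80
    seed: int = 0
    max_sweep_retries: int = 100

    @property
    def chrom_len(self) -> int:
        return self.L // self.n_chrom

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    def layout(self) -> GenomeLayout:
        """Chromosome layout; pericentromeric block = central 40% of each."""
        peri = []
        for name in self.chrom_names():
            peri.append((name, int(0.3 * self.chrom_len), int(0.7 * self.chrom_len)))
        return GenomeLayout(
            chromosomes=[(name, self.chrom_len) for name in self.chrom_names()],
            pericentromeric=peri,
        )

    def validate(self) -> None:
        positive = (
            self.L, self.n_chrom, self.mu, self.rho, self.N_anc, self.N_wild,
            self.N_cul, self.bottleneck_size,
        )
        if any(x <= 0 for x in positive):
            raise ValueError("sizes and rates must be positive")
        if self.T_split < 0 or self.bottleneck_duration < 0:
            raise ValueError("durations must be non-negative")
        if self.bottleneck_duration > self.T_split:
            raise ValueError("bottleneck_duration cannot exceed T_split")
        names = set(self.chrom_names())
        for chrom, pos, s in self.sweep_loci:
            if chrom not in names or not (0 <= pos < self.chrom_len):
                raise ValueError(f"sweep locus outside genome: {(chrom, pos, s)}")
        if self.T_split == 0:
            if self.n_sample_wild + self.n_sample_cul > self.N_anc:
                raise ValueError("cannot sample this many distinct ancestral individuals")
        else:
            if self.n_sample_wild > self.N_wild or self.n_sample_cul > self.N_cul:
                raise ValueError("sample size exceeds population size")


def default_sweep_loci(params: SimParams, s: float = 0.1, n: int = 3) -> tuple:
    """Sweeps at the centre of the first *n* chromosomes."""
    names = params.chrom_names()
    return tuple((names[i], params.chrom_len // 2, s) for i in range(min(n, len(names))))


@dataclasses.dataclass
class SimTruth:
    """Ground truth emitted with every simulated panel."""

    params: SimParams
    sweeps: list[dict] = dataclasses.field(default_factory=list)
    qtls: list[tuple[str, float]] = dataclasses.field(default_factory=list)
    env_effects: dict[str, float] | None = None
    seed: int = 0

    def sweep_windows(self, window: int = 10_000) -> list[tuple[str, int, int]]:
        """The window of *window* bp containing each realized sweep site."""
        out = []
        for sw in self.sweeps:
            start = (sw["position"] // window) * window
            out.append((sw["chrom"], int(start), int(start + window)))
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "params": dataclasses.asdict(self.params),
            "sweeps": self.sweeps,
            "qtls": [[i, float(e)] for i, e in self.qtls],
            "env_effects": self.env_effects,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        payload = json.loads(Path(path).read_text())
        payload["params"]["sweep_loci"] = tuple(
            tuple(x) for x in payload["params"]["sweep_loci"]
        )
        params = SimParams(**payload["params"])
        return cls(
            params=params,
            sweeps=payload["sweeps"],
            qtls=[(i, e) for i, e in payload["qtls"]],
            env_effects=payload["env_effects"],
            seed=payload["seed"],
        )


# ---------------------------------------------------------------------------
# forward Wright-Fisher core
# ---------------------------------------------------------------------------


@njit(cache=True)
def _recombine(H, positions, par_ind, phase0, bps, offs, out):  # pragma: no cover
    """Build gamete haplotypes by walking sites in position order.

    ``par_ind[g]`` is the parent individual of gamete g; ``phase0[g]`` the
    starting parental haplotype; ``bps[offs[g]:offs[g+1]]`` its sorted
    crossover breakpoints.
    """
    n_gam, n_site = out.shape
    for g in range(n_gam):
        a = 2 * par_ind[g] + phase0[g]
        b = 2 * par_ind[g] + (1 - phase0[g])
        k0 = offs[g]
        k1 = offs[g + 1]
        if k1 == k0:
            out[g, :] = H[a, :]
            continue
        cur = a
        other = b
        ptr = k0
        for sidx in range(n_site):
            p = positions[sidx]
            while ptr < k1 and bps[ptr] <= p:
                tmp = cur
                cur = other
                other = tmp
                ptr += 1
            out[g, sidx] = H[cur, sidx]


class _Pop:
    """Forward-simulated population: haplotypes, site positions, fixed set."""

    def __init__(self, H: np.ndarray, positions: np.ndarray):
        self.H = np.ascontiguousarray(H, dtype=np.uint8)
        self.positions = np.asarray(positions, dtype=np.int64)
        self.fixed: set[int] = set()

    @property
    def n_dip(self) -> int:
        return self.H.shape[0] // 2

    def inject(self, position: int, carrier: int) -> None:
        """Add a de novo mutation at *position* carried by one haplotype."""
        i = np.searchsorted(self.positions, position)
        if i < len(self.positions) and self.positions[i] == position:
            raise ValueError(f"position {position} already segregating")
        col = np.zeros((self.H.shape[0], 1), dtype=np.uint8)
        col[carrier, 0] = 1
        self.positions = np.insert(self.positions, i, position)
        self.H = np.ascontiguousarray(np.hstack([self.H[:, :i], col, self.H[:, i:]]))

    def allele_freq(self, position: int) -> float:
        """Population frequency of the derived allele at *position*."""
        if position in self.fixed:
            return 1.0
        i = np.searchsorted(self.positions, position)
        if i < len(self.positions) and self.positions[i] == position:
            return float(self.H[:, i].sum()) / self.H.shape[0]
        return 0.0

    def step(
        self,
        n_off: int,
        rng: np.random.Generator,
        *,
        chrom_len: int,
        rho: float,
        mu: float,
        used_positions: np.ndarray,
        selected: Sequence[tuple[int, float]] = (),
    ) -> None:
        """Advance one Wright-Fisher generation to *n_off* diploids.

        *used_positions* is a chromosome-length boolean occupancy array shared
        between the daughter lineages so a position never hosts two distinct
        mutations.
        """
        n_par = self.n_dip
        n_gam = 2 * n_off
        if selected:
            w = np.ones(n_par)
            for pos, s in selected:
                i = np.searchsorted(self.positions, pos)
                if i < len(self.positions) and self.positions[i] == pos:
                    dos = self.H[0::2, i].astype(np.float64) + self.H[1::2, i]
                    w *= (1.0 + s) ** dos
            par = rng.choice(n_par, size=n_gam, p=w / w.sum())
        else:
            par = rng.integers(0, n_par, size=n_gam)
        phase0 = rng.integers(0, 2, size=n_gam)
        nx = rng.poisson(rho * chrom_len, size=n_gam)
        offs = np.zeros(n_gam + 1, dtype=np.int64)
        np.cumsum(nx, out=offs[1:])
        bps = rng.integers(0, chrom_len, size=int(offs[-1]))
        for g in np.flatnonzero(nx > 1):
            bps[offs[g] : offs[g + 1]].sort()
        out = np.empty((n_gam, len(self.positions)), dtype=np.uint8)
        _recombine(
            self.H,
            self.positions,
            par.astype(np.int64),
            phase0.astype(np.int64),
            bps.astype(np.int64),
            offs,
            out,
        )
        # new mutations: one derived copy on a random gamete each
        n_new = int(rng.poisson(2 * n_off * mu * chrom_len))
        pieces: list[np.ndarray] = []
        got = 0
        while got < n_new:
            cand = rng.integers(0, chrom_len, size=(n_new - got) + 8)
            cand = np.unique(cand[~used_positions[cand]])[: n_new - got]
            if cand.size:
                used_positions[cand] = True
                pieces.append(cand)
                got += cand.size
        new_pos = (
            np.sort(np.concatenate(pieces)) if pieces else np.empty(0, dtype=np.int64)
        )
        carriers = rng.integers(0, n_gam, size=new_pos.size)
        # prune lost/fixed columns and merge in the new mutations, keeping
        # positions sorted (the kernel requires ascending site order)
        freq = out.sum(axis=0, dtype=np.int64)
        keep = (freq > 0) & (freq < n_gam)
        for p in self.positions[freq == n_gam]:
            self.fixed.add(int(p))
        kept_pos = self.positions[keep]
        if new_pos.size:
            n_keep = int(keep.sum())
            ins = np.searchsorted(kept_pos, new_pos)
            new_target = ins + np.arange(new_pos.size)
            kept_target = np.delete(np.arange(n_keep + new_pos.size), new_target)
            merged = np.empty(n_keep + new_pos.size, dtype=np.int64)
            merged[kept_target] = kept_pos
            merged[new_target] = new_pos
            H2 = np.zeros((n_gam, merged.size), dtype=np.uint8)
            H2[:, kept_target] = out[:, keep]
            H2[carriers, new_target] = 1
            self.positions = merged
            self.H = H2
        else:
            self.positions = kept_pos
            self.H = np.ascontiguousarray(out[:, keep])


def _ancestral_panel(params: SimParams, msp_seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Equilibrium ancestral haplotypes (2*N_anc x S) and site positions."""
    import msprime

    ts = msprime.sim_ancestry(
        samples=params.N_anc,
        population_size=params.N_anc,
        sequence_length=params.chrom_len,
        recombination_rate=params.rho,
        model=[
            msprime.DiscreteTimeWrightFisher(duration=min(500, 10 * params.N_anc)),
            msprime.StandardCoalescent(),
        ],
        random_seed=msp_seed,
    )
    ts = msprime.sim_mutations(
        ts,
        rate=params.mu,
        random_seed=msp_seed + 1,
        model=msprime.BinaryMutationModel(),
        discrete_genome=True,
    )
    G = ts.genotype_matrix().T.astype(np.uint8)  # haplotypes x sites, 0/1
    positions = ts.sites_position.astype(np.int64)
    # drop duplicate positions (possible under a discrete genome) and sites
    # monomorphic after back-mutation
    _, first = np.unique(positions, return_index=True)
    G = G[:, first]
    positions = positions[first]
    freq = G.sum(axis=0)
    seg = (freq > 0) & (freq < G.shape[0])
    return np.ascontiguousarray(G[:, seg]), positions[seg]


def _simulate_chrom(
    params: SimParams,
    chrom: str,
    sweeps: list[tuple[int, float]],
    seed_seq: np.random.SeedSequence,
) -> dict:
    """Simulate one chromosome; returns sampled haplotypes for both pops."""
    msp_seed, wild_seed, cul_seed, sample_seed = (
        int(s.generate_state(1)[0] % (2**31 - 2)) + 1 for s in seed_seq.spawn(4)
    )
    A, anc_pos = _ancestral_panel(params, msp_seed)
    clen = params.chrom_len
    sample_rng = np.random.default_rng(sample_seed)

    if params.T_split == 0:
        n = params.n_sample_wild + params.n_sample_cul
        inds = sample_rng.choice(params.N_anc, size=n, replace=False)
        rows = np.stack([2 * inds, 2 * inds + 1], axis=1).reshape(-1)
        hap = A[rows]
        freq = hap.sum(axis=0)
        seg = (freq > 0) & (freq < hap.shape[0])
        k = 2 * params.n_sample_wild
        return {
            "positions": anc_pos[seg],
            "wild_hap": hap[:k, seg],
            "cul_hap": hap[k:, seg],
            "sweeps": [],
        }

    used = np.zeros(clen, dtype=bool)
    used[anc_pos] = True
    # sweeps are de novo domestication alleles: a new mutation at the
    # requested position, injected into one founding cultivated haplotype
    sweep_sites = []
    for target, s in sweeps:
        pos = int(target)
        while used[pos]:  # position already hosts a segregating site
            pos += 1
        used[pos] = True
        sweep_sites.append(
            {"chrom": chrom, "target": int(target), "position": pos, "s": float(s)}
        )

    # wild lineage: constant size, neutral
    wild = _Pop(A, anc_pos)
    wild_rng = np.random.default_rng(wild_seed)
    wild_used = used.copy()
    for _ in range(params.T_split):
        wild.step(
            params.N_wild, wild_rng, chrom_len=clen, rho=params.rho, mu=params.mu,
            used_positions=wild_used,
        )

    # cultivated lineage: bottleneck, recovery, selection; retry on loss
    selected = [(sw["position"], sw["s"]) for sw in sweep_sites]
    cul_ss = np.random.SeedSequence(cul_seed)
    cul = None
    for _attempt in range(max(1, params.max_sweep_retries)):
        attempt_rng = np.random.default_rng(cul_ss.spawn(1)[0])
        pop = _Pop(A, anc_pos)
        pop_used = used.copy()
        lost = False
        for g in range(params.T_split):
            n_off = (
                params.bottleneck_size
                if g < params.bottleneck_duration
                else params.N_cul
            )
            pop.step(
                n_off, attempt_rng, chrom_len=clen, rho=params.rho, mu=params.mu,
                used_positions=pop_used, selected=selected,
            )
            if g == 0:
                for pos, _s in selected:
                    pop.inject(pos, int(attempt_rng.integers(0, 2 * n_off)))
            elif selected and any(pop.allele_freq(pos) == 0 for pos, _ in selected):
                lost = True  # abort early; most losses happen within a few generations
                break
        if not lost:
            cul = pop
            break
    if cul is None:
        raise SweepLostError(
            f"sweep allele lost on {chrom} in {params.max_sweep_retries} attempts"
        )
    for sw in sweep_sites:
        sw["final_freq"] = cul.allele_freq(sw["position"])

    def _sample(pop: _Pop, n: int) -> tuple[np.ndarray, np.ndarray, set[int]]:
        inds = sample_rng.choice(pop.n_dip, size=n, replace=False)
        rows = np.stack([2 * inds, 2 * inds + 1], axis=1).reshape(-1)
        return pop.positions, pop.H[rows], pop.fixed

    w_pos, w_hap, w_fixed = _sample(wild, params.n_sample_wild)
    c_pos, c_hap, c_fixed = _sample(cul, params.n_sample_cul)

    # merge the two site registries (segregating plus fixed-derived)
    all_pos = np.array(
        sorted(set(w_pos.tolist()) | set(c_pos.tolist()) | w_fixed | c_fixed),
        dtype=np.int64,
    )

    def _expand(pos, hap, fixed, n_hap):
        out = np.zeros((n_hap, len(all_pos)), dtype=np.uint8)
        idx = np.searchsorted(all_pos, pos)
        out[:, idx] = hap
        if fixed:
            fixed_idx = np.searchsorted(all_pos, np.array(sorted(fixed), dtype=np.int64))
            out[:, fixed_idx] = 1
        return out

    W = _expand(w_pos, w_hap, w_fixed, 2 * params.n_sample_wild)
    C = _expand(c_pos, c_hap, c_fixed, 2 * params.n_sample_cul)
    tot = W.sum(axis=0, dtype=np.int64) + C.sum(axis=0, dtype=np.int64)
    seg = (tot > 0) & (tot < W.shape[0] + C.shape[0])
    return {
        "positions": all_pos[seg],
        "wild_hap": W[:, seg],
        "cul_hap": C[:, seg],
        "sweeps": sweep_sites,
    }


def simulate_two_pop(
    params: SimParams, reference: dict[str, str] | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame, SimTruth]:
    """Simulate the wild/cultivated panel.

    Returns the sampled genotype matrix (derived allele = ALT), the sample
    metadata table, and the ground truth (realized sweep sites and QTLs).
    """
    params.validate()
    ss = np.random.SeedSequence(params.seed)
    chrom_children = ss.spawn(params.n_chrom)
    misc_rng = np.random.default_rng(ss.spawn(1)[0])

    per_chrom_sweeps: dict[str, list[tuple[int, float]]] = {c: [] for c in params.chrom_names()}
    for chrom, pos, s in params.sweep_loci:
        per_chrom_sweeps[chrom].append((int(pos), float(s)))

    frames = []
    dosage_blocks = []
    sweeps: list[dict] = []
    for chrom, child in zip(params.chrom_names(), chrom_children):
        res = _simulate_chrom(params, chrom, per_chrom_sweeps[chrom], child)
        sweeps.extend(res["sweeps"])
        hap = np.concatenate([res["wild_hap"], res["cul_hap"]], axis=0)
        dos = (hap[0::2] + hap[1::2]).T.astype(np.int8)  # variants x samples
        pos = res["positions"]
        if reference is not None:
            seq = reference[chrom]
            ref = np.array([seq[p] for p in pos])
            alt = np.array(
                [misc_rng.choice([b for b in "ACGT" if b != r]) for r in ref]
            )
        else:
            ref = np.full(len(pos), "A")
            alt = np.full(len(pos), "C")
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "id": [f"{chrom}_{p + 1}" for p in pos],
                    "ref": ref,
                    "alt": alt,
                }
            )
        )
        dosage_blocks.append(dos)

    wild_names = [f"W{i + 1:03d}" for i in range(params.n_sample_wild)]
    cul_names = [f"C{i + 1:03d}" for i in range(params.n_sample_cul)]
    samples = wild_names + cul_names
    m = GenotypeMatrix(
        variants=pd.concat(frames, ignore_index=True),
        samples=samples,
        dosage=np.concatenate(dosage_blocks, axis=0),
    )
    m.validate()

    evo = ["wild"] * len(wild_names) + [
        str(misc_rng.choice(["landrace", "improved"], p=[0.75, 0.25]))
        for _ in cul_names
    ]
    eco = [str(misc_rng.choice(["NR", "HR", "SR"])) for _ in samples]
    meta = make_metadata(
        samples,
        ["wild"] * len(wild_names) + ["cultivated"] * len(cul_names),
        evolution_type=evo,
        eco_region=eco,
    )

    truth = SimTruth(params=params, sweeps=sweeps, seed=params.seed)
    if params.n_qtl > 0:
        from .popgen_stats import site_stats

        st = site_stats(m, cul_names)
        cand = np.flatnonzero(np.nan_to_num(st["maf"].to_numpy(), nan=0.0) >= 0.10)
        if cand.size:
            take = misc_rng.choice(cand, size=min(params.n_qtl, cand.size), replace=False)
            effects = misc_rng.normal(0.0, params.qtl_effect_sd, size=take.size)
            ids = m.variants["id"].to_numpy()
            truth.qtls = [(str(ids[i]), float(e)) for i, e in zip(take, effects)]
    return m, meta, truth


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def breeding_values(
    m: GenotypeMatrix, qtls: Sequence[tuple[str, float]], samples: Sequence[str] | None = None
) -> pd.Series:
    """Additive genetic value per sample, sum of effect x dosage over QTLs."""
    names = list(samples) if samples is not None else list(m.samples)
    idx = m.sample_indices(names)
    id_row = {v: i for i, v in enumerate(m.variants["id"])}
    bv = np.zeros(len(names))
    for snp_id, effect in qtls:
        if snp_id not in id_row:
            raise ValueError(f"QTL {snp_id} not among SNPs")
        d = m.dosage[id_row[snp_id], idx].astype(float)
        miss = d == MISSING
        if miss.any():
            d[miss] = d[~miss].mean() if (~miss).any() else 0.0
        bv += effect * d
    return pd.Series(bv, index=names, name="breeding_value")


def simulate_phenotypes(
    m: GenotypeMatrix,
    truth: SimTruth,
    n_env: int = 9,
    h2: float = 0.8,
    seed: int = 0,
    n_rep: int = 3,
    samples: Sequence[str] | None = None,
    baseline: float = 15.0,
) -> pd.DataFrame:
    """Multi-environment 100-seed-weight table (sample, environment, replicate).

    phenotype = baseline + breeding value + environment main effect + GxE
    noise + replicate residual.  The non-genetic variance is split 40% / 20% /
    40% between those three terms and scaled so the genetic fraction of the
    single-observation variance equals *h2* in expectation.  Environment main
    effects are recorded in ``truth.env_effects``.
    """
    if not (0 < h2 <= 1):
        raise ValueError("h2 must be in (0, 1]")
    rng = np.random.default_rng(seed)
    names = list(samples) if samples is not None else list(m.samples)
    bv = breeding_values(m, truth.qtls, names).to_numpy()
    v_g = float(np.var(bv)) if len(truth.qtls) else 0.0
    if v_g > 0 and h2 < 1:
        v_ng = v_g * (1.0 - h2) / h2
    elif v_g == 0:
        v_ng = 1.0  # pure-noise phenotype; scale is arbitrary
    else:
        v_ng = 0.0
    env_sd = np.sqrt(0.4 * v_ng)
    gxe_sd = np.sqrt(0.2 * v_ng)
    res_sd = np.sqrt(0.4 * v_ng)

    envs = [f"E{i + 1}" for i in range(n_env)]
    env_eff = rng.normal(0.0, env_sd, size=n_env) if env_sd > 0 else np.zeros(n_env)
    truth.env_effects = {e: float(v) for e, v in zip(envs, env_eff)}
    gxe = (
        rng.normal(0.0, gxe_sd, size=(len(names), n_env))
        if gxe_sd > 0
        else np.zeros((len(names), n_env))
    )
    rows = []
    for j, env in enumerate(envs):
        for k in range(n_rep):
            res = (
                rng.normal(0.0, res_sd, size=len(names))
                if res_sd > 0
                else np.zeros(len(names))
            )
            y = baseline + bv + env_eff[j] + gxe[:, j] + res
            for i, name in enumerate(names):
                rows.append((name, env, k + 1, max(float(y[i]), 0.1)))
    return pd.DataFrame(
        rows, columns=["sample", "environment", "replicate", "hundred_seed_weight"]
    )


# ---------------------------------------------------------------------------
# reference sequence and fake annotation
# ---------------------------------------------------------------------------


def random_reference(layout: GenomeLayout, seed: int = 0) -> dict[str, str]:
    """Random ACGT reference sequences matching *layout* (deterministic)."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    return {
        chrom: "".join(bases[rng.integers(0, 4, size=length)])
        for chrom, length in layout.chromosomes
    }


def tile_genes(
    layout: GenomeLayout, gene_length: int = 3_000, spacing: int = 10_000
) -> GeneSet:
    """Deterministic fake annotation: genes tiled every *spacing* bp.

    Each gene has UTR5 / CDS / intron / CDS / UTR3 sub-features (10%, 35%,
    15%, 30%, 10% of the span) so the context classifier has every class to
    hit.
    """
    genes, feats = [], []
    for chrom, length in layout.chromosomes:
        k = 0
        for start in range(spacing // 4, length - gene_length, spacing):
            gid = f"g{chrom[3:] if chrom.startswith('chr') else chrom}_{k:05d}"
            end = start + gene_length
            strand = "+" if k % 2 == 0 else "-"
            genes.append((gid, chrom, start, end, strand))
            cuts = [0.0, 0.10, 0.45, 0.60, 0.90, 1.0]
            kinds = ["UTR5", "CDS", "intron", "CDS", "UTR3"]
            bounds = [start + int(c * gene_length) for c in cuts]
            for kind, a, b in zip(kinds, bounds[:-1], bounds[1:]):
                feats.append((gid, kind, a, b))
            k += 1
    gs = GeneSet(
        genes=pd.DataFrame(genes, columns=["id", "chrom", "start", "end", "strand"]),
        features=pd.DataFrame(feats, columns=["gene_id", "kind", "start", "end"]),
    )
    gs.validate()
    return gs
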