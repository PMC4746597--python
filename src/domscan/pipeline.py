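"""End-to-end orchestration on a simulated panel.

``run_all`` executes simulate -> window stats -> LD decay -> sweep scan ->
structure/phylogeny -> array design -> GWAS on one simulated wild/cultivated
panel and writes every stage's table plus a machine-readable ``metrics.json``
into the report directory.  Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    array_design,
    association,
    io_model,
    linkage,
    popgen_stats,
    simulate,
    structure_phylo,
    sweep_scan,
)

log = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Pipeline configuration with the study's default window sizes."""

    out_dir: str = "domscan_run"
    seed: int = 0
    # simulator
    sim: simulate.SimParams = dataclasses.field(default_factory=simulate.SimParams)
    n_sweeps: int = 3
    sweep_s: float = 0.1
    # analysis windows
    stats_window: int = 100_000
    sweep_window: int = 10_000
    quantile: float = 0.95
    design_window: int = 1_680
    # LD
    ld_max_dist: int = 1_000_000
    ld_bin: int = 1_000
    # thresholds
    gwas_maf_min: float = 0.05
    design_maf_min: float = 0.10
    half_decay_override: int | None = None
    # phenotype
    n_env: int = 9
    h2: float = 0.8

    def validate(self) -> None:
        if not (0 <= self.quantile < 1):
            raise ValueError("quantile must be in [0,1)")
        if not (0 < self.h2 <= 1):
            raise ValueError("h2 must be in (0,1]")
        for x in (self.stats_window, self.sweep_window, self.design_window, self.ld_bin):
            if x <= 0:
                raise ValueError("window sizes must be positive")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        sim_raw = raw.pop("sim", {})
        if "sweep_loci" in sim_raw:
            sim_raw["sweep_loci"] = tuple(tuple(x) for x in sim_raw["sweep_loci"])
        cfg = cls(**raw)
        cfg.sim = simulate.SimParams(**sim_raw)
        return cfg

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def run_all(config: RunConfig) -> dict:
    """Run the full pipeline; returns the metrics dict written to disk."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config.to_json(), indent=1))

    params = dataclasses.replace(config.sim, seed=config.seed)
    if config.n_sweeps and not params.sweep_loci:
        params = dataclasses.replace(
            params,
            sweep_loci=simulate.default_sweep_loci(params, s=config.sweep_s, n=config.n_sweeps),
        )
    layout = params.layout()
    reference = simulate.random_reference(layout, seed=config.seed)
    genes = simulate.tile_genes(layout)

    log.info("simulate: %d bp x %d chrom, seed %d", params.L, params.n_chrom, config.seed)
    m, meta, truth = simulate.simulate_two_pop(params, reference=reference)
    io_model.write_genotypes(m, out / "panel.vcf", layout)
    io_model.write_metadata(meta, out / "panel_meta.tsv")
    io_model.write_genes(genes, out / "genes.gff3")
    truth.to_json(out / "truth.json")
    log.info("simulate: %d SNPs x %d samples", m.n_variants, m.n_samples)

    metrics: dict = {"seed": config.seed, "n_snps": m.n_variants, "n_samples": m.n_samples}

    # diversity statistics at the broad window size
    stats = popgen_stats.window_stats(m, meta, layout, config.stats_window)
    io_model.write_windows(stats, out / "window_stats.tsv")
    metrics["pi_wild_mean"] = float(np.nanmean(stats["pi_wild"]))
    metrics["pi_cul_mean"] = float(np.nanmean(stats["pi_cul"]))
    metrics["tajd_wild_mean"] = float(np.nanmean(stats["tajd_wild"]))
    metrics["tajd_cul_mean"] = float(np.nanmean(stats["tajd_cul"]))
    part = popgen_stats.shared_unique_partition(m, meta)
    total = sum(part.values())
    metrics["snp_partition"] = part
    metrics["snp_partition_pct"] = {k: round(100 * v / total, 2) for k, v in part.items()}

    # LD decay per population
    half = {}
    for pop in ("wild", "cultivated"):
        curve = linkage.ld_decay(
            m,
            io_model.population_samples(meta, pop),
            max_dist=config.ld_max_dist,
            bin_width=config.ld_bin,
        )
        pd.DataFrame(
            {"center": curve.centers, "mean_r2": curve.mean_r2, "n_pairs": curve.counts}
        ).to_csv(out / f"ld_decay_{pop}.tsv", sep="\t", index=False)
        half[pop] = linkage.half_decay_distance(curve)
    metrics["half_decay_wild_bp"] = half["wild"]
    metrics["half_decay_cul_bp"] = half["cultivated"]

    # sweep scan
    scan = sweep_scan.scan_windows(m, meta, layout, config.sweep_window)
    called = sweep_scan.call_selection_windows(scan, q=config.quantile)
    regions = sweep_scan.merge_called(called)
    sweep_scan.annotate_regions(regions, genes)
    io_model.write_windows(called, out / "sweep_windows.tsv")
    io_model.write_regions(regions, out / "sweep_regions.bed")
    n_called = int(called["called"].sum())
    metrics["sweep_called_windows"] = n_called
    metrics["sweep_regions"] = len(regions)
    metrics["sweep_genome_fraction_pct"] = sweep_scan.genome_fraction(regions, layout)
    metrics["sweep_genes"] = len(sweep_scan.region_gene_ids(regions))
    truth_windows = truth.sweep_windows(config.sweep_window)
    called_keys = set(
        zip(called.loc[called["called"], "chrom"], called.loc[called["called"], "start"])
    )
    metrics["true_sweeps_recovered"] = sum(
        (c, s) in called_keys for c, s, _e in truth_windows
    )
    metrics["true_sweeps_total"] = len(truth_windows)

    # structure and phylogeny
    dm = structure_phylo.ibs_distance(m)
    coords, var_frac = structure_phylo.pca_coords(m, k=5)
    newick = structure_phylo.nj_tree(dm)
    io_model.write_tree(newick, out / "nj_tree.nwk")
    pc = pd.DataFrame(coords, columns=[f"PC{i+1}" for i in range(coords.shape[1])])
    pc.insert(0, "sample", m.samples)
    pc.to_csv(out / "pca_coords.tsv", sep="\t", index=False)
    wild_mask = meta.set_index("sample").loc[m.samples, "population"].to_numpy() == "wild"
    pc1 = coords[:, 0]
    sep = abs(np.corrcoef(pc1, wild_mask.astype(float))[0, 1])
    metrics["pc1_population_correlation"] = float(sep)
    metrics["pc_variance_fractions"] = [float(x) for x in var_frac]

    # array design
    design = array_design.run_design(
        m, reference, genes, layout,
        maf_min=config.design_maf_min, fill_window=config.design_window,
    )
    design.table.to_csv(out / "array_design.tsv", sep="\t", index=False)
    context = io_model.classify_snp_context(m, genes)
    context.index = m.variants["id"]
    summary = array_design.design_summary(design, layout, genes=genes, context=context)
    metrics["design"] = {
        k: v for k, v in summary.items() if not isinstance(v, dict)
    }

    # GWAS on the cultivated panel
    cul = io_model.population_samples(meta, "cultivated")
    pheno = simulate.simulate_phenotypes(
        m, truth, n_env=config.n_env, h2=config.h2, seed=config.seed, samples=cul
    )
    pheno.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    blup = association.blup_phenotype(pheno)
    res = association.mlm_scan(
        m.subset_samples(cul), blup, maf_min=config.gwas_maf_min
    )
    res.table.to_csv(out / "gwas.tsv", sep="\t", index=False)
    metrics["gwas_n_markers"] = res.n_markers
    metrics["gwas_threshold"] = res.threshold
    hits = res.significant
    metrics["gwas_hits"] = len(hits)
    if len(hits):
        hd = config.half_decay_override or half["cultivated"] or 130_000
        regions = association.candidate_regions(hits, int(hd), genes=genes, layout=layout)
        metrics["gwas_regions"] = len(regions)
        with open(out / "gwas_regions.json", "w") as fh:
            json.dump(regions, fh, indent=1)

    (out / "metrics.json").write_text(json.dumps(metrics, indent=1, sort_keys=True))
    return metrics
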