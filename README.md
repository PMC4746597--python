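# domscan

Detecting crop-domestication signatures from SNP genotypes.

Domestication leaves characteristic marks in a crop's genome relative to its
wild progenitor: reduced nucleotide diversity (the derived population passed
through a bottleneck), negative Tajima's D (post-bottleneck expansion and
sweeps skew the frequency spectrum), longer linkage disequilibrium, and —
at artificially selected loci — windows where diversity collapsed and
differentiation spiked.  `domscan` implements the full analytical chain used
in soybean-style domestication studies for population geneticists and
breeders working with biallelic SNP panels (VCF + sample metadata + GFF3):

* **popgen_stats** — windowed π, Tajima's D, MAF, Weir–Cockerham F_ST and
  the reduction-of-diversity statistic **ROD = 1 − π_cul/π_wild**;
* **sweep_scan** — the composite selection scan: a 10-kb window is a
  domestication-selection window iff it lies in the upper 5% tail of the
  pooled empirical distributions of *both* ROD and F_ST; adjacent called
  windows are merged and annotated with overlapping genes;
* **linkage** — pairwise r² (composite, unphased dosages), LD-decay curves
  and the half-decay distance;
* **array_design** — a genotyping-array SNP selection pipeline
  (MAF/missingness filter, 33-mer flank uniqueness, greedy tag SNPs at
  r² ≥ 0.8, 1,680-bp even-coverage fill with genic preference, VIP
  supplementation) with recomputable coverage summaries;
* **structure_phylo** — IBS distances, frequency-scaled PCA, Saitou–Nei
  neighbor joining with Newick output;
* **association** — multi-environment BLUP breeding values (EM-REML), the
  VanRaden kinship matrix, an exact mixed-linear-model GWAS with five PC
  covariates and the 1/n significance threshold, and LD-sized candidate
  regions around lead SNPs;
* **simulate** — a two-population Wright–Fisher domestication simulator
  (coalescent-initialised, forward from the split, hard sweeps with retry
  on loss, multi-environment additive phenotypes) so the whole pipeline is
  testable end to end without any external data.

## Worked example

Simulate a domestication panel and scan it:

```sh
domscan run --seed 1 --out demo
```

which simulates a 5-Mb panel of 40 wild and 80 cultivated accessions and
runs windowed stats → LD → sweep scan → structure → array design → GWAS
(~40 s on one CPU).  Selected metrics it prints with seed 1:

```
"n_snps": 14220,            "n_samples": 120,
"pi_wild_mean": 3.97e-04,   "pi_cul_mean": 2.46e-04,
"tajd_wild_mean": -0.008,   "tajd_cul_mean": -0.192,
"half_decay_wild_bp": 9182, "half_decay_cul_bp": 11286,
"sweep_called_windows": 6,  "sweep_genome_fraction_pct": 1.2,
"true_sweeps_recovered": 1, "true_sweeps_total": 3,
"pc1_population_correlation": 0.998,
"gwas_n_markers": 3298,     "gwas_threshold": 3.03e-04,  "gwas_hits": 23
```

Reading this: the cultivated population retains ~62% of wild diversity
(the 10% bottleneck), its Tajima's D is clearly more negative (recovery
expansion plus sweeps), and its LD decays more slowly; the composite scan
calls 6 windows (1.2% of this small genome) of which one contains a
planted sweep — drift in a bottlenecked population mimics sweeps, so
recovery through the joint 5% tails is intrinsically partial (see
`docs/methods.md`); PC1 separates the populations essentially perfectly;
and the three planted seed-weight QTLs give 23 SNPs below the 1/n
threshold (the hits cluster around the QTLs in LD).  Exact numbers vary
with the seed; the library functions behind each stage are importable
directly (`domscan.popgen_stats.window_stats`,
`domscan.sweep_scan.call_selection_windows`,
`domscan.association.mlm_scan`, ...).

Equivalent per-stage commands: `domscan simulate`, `domscan stats`,
`domscan ld`, `domscan sweep`, `domscan structure`, `domscan design`,
`domscan gwas`, `domscan io-validate`.

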