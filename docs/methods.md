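# Methods

`domscan` re-implements, as a tested pipeline over simulated data, the
analytical chain used to detect domestication signatures in crop SNP panels:
windowed diversity statistics, a composite ROD + F_ST selective-sweep scan,
LD decay, genotyping-array SNP selection, population structure, and a
mixed-linear-model GWAS.  This note records the models, the defaults and why
they were chosen, the numerical decisions, and what the synthetic data can
and cannot establish.

## Statistics

**Per-site diversity.**  For a biallelic site with `c` called alleles and
alternate frequency `p`, the unbiased per-site heterozygosity is
`pi_site = 2 p (1-p) c / (c-1)`, which equals the mean pairwise difference
over all C(c,2) allele pairs.  Windowed pi sums `pi_site` over the window's
sites and divides by the window length in bp, so windows of different SNP
density are comparable.  Windows are non-overlapping tiles; the last tile of
a chromosome is truncated at the chromosome end and normalised by its true
span.

**Tajima's D** uses the 1989 constants (a1, a2, b1, b2, c1, c2, e1, e2)
computed from a single allele count `n`.  When missingness makes the called
count vary across a window's sites, `n` is the median count over the
window's segregating sites (rounded); a window with no segregating site has
no D (reported missing, never 0).

**F_ST** is the Weir & Cockerham (1984) two-population estimator.  Per-site
variance components (a, b, c) are combined per window as
`sum(a) / sum(a+b+c)` (ratio of sums), which is stable in low-diversity
windows where mean-of-ratios is not.  Sites where either population has no
called genotype, or where a+b+c = 0, are skipped.

**ROD** = 1 − pi_cultivated / pi_wild per window; undefined when pi_wild =
0.  Undefined windows are excluded from all percentile pools and can never
be called — ROD is the domestication signal, and a window with no wild
diversity carries none.

**Sweep calling.**  Over windows where both statistics are defined, the
threshold for each statistic is its k-th largest value with
k = floor((1−q)·n_defined) (nearest-rank from the top; q defaults to 0.95).
A window is called iff it reaches both thresholds; ties at a threshold are
included, and q = 0 degenerates to calling every defined window.  Adjacent
(book-ended) called windows merge into sweep regions; the merge tolerates no
gaps (a gap-tolerant merge is a config knob deliberately left at 0).  A gene
is credited to a region if their spans overlap by at least 1 bp, and counted
once even when it spans two regions.

**LD.**  r² is the squared Pearson correlation of dosage vectors over
samples called at both sites (the composite estimate appropriate for
unphased genotypes); pairs never cross chromosomes, and pairs with a
monomorphic member or fewer than 3 shared calls are skipped.  The decay
curve bins pairs by distance (default 1-kb bins to 1 Mb).  The curve maximum
is defined as the first populated bin's mean — under decay r² is maximal at
short range, and this avoids noise-driven maxima at long range.  The
half-decay distance interpolates linearly between the populated bins
straddling half of that maximum.

**IBS distance** scores each co-called site 1 for identical genotypes, 0.5
for a one-allele match and 0 for opposite homozygotes (score =
1 − |d_i − d_j|/2) and takes one minus the mean.  **PCA** standardises each
polymorphic SNP as (g − 2p)/sqrt(2p(1−p)) with per-SNP mean imputation of
missing calls; coordinates are sign-fixed by making each component's
largest-magnitude entry positive.  **Neighbor joining** is the Saitou–Nei
agglomeration with standard branch lengths; a negative branch length is
clamped to zero and its deficit moved to the sibling edge so the joined
pair's path length is preserved.

**BLUP phenotypes.**  Multi-environment trials are reduced to one breeding
value per accession with the two-way mixed model
y = mu + environment (fixed) + genotype (random iid) + error.  Variance
components come from EM-REML on the mixed-model equations iterated to
relative tolerance 1e-6; the genotype random-effect predictions are the GWAS
phenotype.  The variance ratio in the equations is floored at 1e-8 because
the equations lose rank at the zero-residual boundary (the environment and
genotype designs share the intercept); reaching that boundary is treated as
convergence.  For balanced data the estimates coincide with the closed-form
ANOVA/REML solution, which the tests verify.

**Kinship and the MLM scan.**  K = ZZ'/(2 Σ p(1−p)) with Z = dosage − 2p
and per-SNP mean imputation (VanRaden).  The association model is the exact
single-marker mixed model y = Xβ + g·b + u + e with u ~ (0, K σ_g²), X an
intercept plus the first five genotype PCs.  The variance ratio
δ = σ_e²/σ_g² is estimated once on the null model by REML, profiled over δ
on the spectral decomposition of K, and reused for every marker; each marker
then gets a GLS Wald test (t distribution, n − p − 1 df).  This is the
standard exact-MLM scheme with null-model variance components; the
"compressed" grouping of the original tool is an efficiency device, not a
statistical claim, and is not reproduced.  Markers with MAF < 0.05 or call
rate < 0.9 are excluded before testing; the significance threshold is
1/n_markers (reported to 3 significant figures).  Candidate regions extend
each significant SNP by the population's LD half-decay distance on both
sides, clipped at chromosome ends, with overlapping regions merged and the
smallest-p SNP reported as the lead.

**Array design.**  Candidates need MAF ≥ 0.10 and missingness ≤ 0.2.  (The
source protocol's filter sentence is self-contradictory as printed; this
reading — keep common, well-genotyped SNPs — is the only one that retains
informative markers.)  Flank uniqueness requires the 33-mer centred on the
SNP to occur exactly once in the reference, counting both strands; SNPs
within 16 bp of a contig end are non-evaluable and dropped.  Tag selection
is greedy maximum coverage: repeatedly pick the candidate tagging (r² ≥ 0.8
within a 500-kb window) the most untagged candidates, leftmost position on
ties, until every candidate is tagged.  Coverage fill tiles the genome with
1,680-bp windows; a window with candidates but no tag receives exactly one,
genic preferred over intergenic, nearest the window centre.  VIP SNPs are
unioned last and bypass the earlier filters (they are supplements, not
candidates).  Summary metrics define mean spacing as total chromosome
length over mapped SNP count.

## The synthetic two-population panel

The generator emulates a wild progenitor and a derived cultivated
population separated by a domestication bottleneck, with hard selective
sweeps in the cultivated lineage and additive multi-environment phenotypes.

*Initialisation.*  The ancestral equilibrium population is drawn with a
seeded msprime simulation (discrete-time Wright–Fisher for the recent 500
generations, standard coalescent beyond), giving an exact stationary sample
without spending a 10·N burn-in in the forward engine.  From the split
onward everything is an explicit forward Wright–Fisher process —
fitness-weighted multinomial parent sampling, Poisson crossovers at a
uniform rate, Poisson new mutations at unoccupied positions — so sweeps and
the bottleneck act mechanically on one daughter lineage.

*Sweeps.*  Each requested sweep is a de novo beneficial mutation placed at
the requested position on one founding cultivated haplotype (fitness 1+s
per copy), the classic hard-sweep model of a domestication allele.  An
allele lost to drift aborts the attempt immediately (losses happen within a
few generations) and the cultivated lineage is re-run with a fresh stream,
up to `max_sweep_retries`; the truth object records the realized position
and final frequency.

*Default demography.*  The defaults are desk-scale placeholders — soybean
demographic parameters are not inferred — chosen so the panel expresses the
qualitative domestication signatures: genome 5 Mb over 5 chromosomes;
mutation rate 2e-7 and crossover rate 2e-7 per bp per generation; all three
populations 500 diploids; split 110 generations ago with a bottleneck of 50
diploids (10%) for the first 50 generations; samples of 40 wild and 80
cultivated accessions.  The compressed timescale keeps every epoch a
meaningful fraction of 2N generations: the bottleneck (0.5 coalescent units
of its own size) depresses cultivated diversity and raises LD; the 60
recovery generations replenish rare variants, driving cultivated Tajima's D
negative; sweeps approach or reach fixation shortly before sampling, so
their footprints have had little time to refill, and the haplotype blocks
of sweeps still completing contribute to the elevated cultivated LD — the
same mechanism the original study invokes.  Mutational refill after
fixation is the irreducible cost of timescale compression: a window swept
at generation t retains ~(T−t)/(2N_anc) of wild diversity, which is why
the split is kept short.

*Phenotypes.*  Each QTL is a SNP with an effect in grams; breeding value =
Σ effect·dosage.  Observations add an environment main effect, a
genotype-by-environment term and a replicate residual, with the non-genetic
variance split 40/20/40 among them and scaled so the genetic share of the
single-observation variance equals the requested heritability (default 0.8
— seed weight is highly heritable).  The baseline of 15 g matches a typical
cultivated 100-seed weight; weights are floored at 0.1 g to respect the
positivity invariant.

*What the generator does not emulate.*  Selfing (soybean is predominantly
autogamous), heterogeneous recombination (no pericentromeric suppression —
the layout's pericentromeric intervals are annotation only), genotyping
error and ascertainment bias of an array, population structure within
either population, eco-geographic differentiation, and linked background
selection.  Passing tests therefore establish the correctness and
calibration of the statistics and the qualitative direction of
domestication contrasts, not quantitative agreement with real soybean data
— the published panel's absolute numbers (80 vs 130 kb half-decay, 1,614
windows) depend on data that were not released.

## Problem sizes used in the test suite

Unit tests run on hand-built fixtures and small panels (0.2–2 Mb, N ≤ 300).
The acceptance suite runs the full stated conditions — 5 Mb, N = 500 per
population, 3 sweeps with s = 0.1, 10% bottleneck — with 20 seeded
replicates shared between the sweep-recovery and domestication-signature
checks, plus 4 no-sweep replicates for the false-positive rate, and a
300-sample equilibrium panel for GWAS calibration.  The estimator-oracle
checks use 50 random micro-fixtures per statistic at tolerance 1e-10.

## Known limitations

* Sweep recovery through the joint ROD + F_ST 95% tails is intrinsically
  noisy at this genome size: a 10% bottleneck drifts some neutral windows
  to the same signature as a completed sweep, and 10-kb windows carry few
  enough SNPs that the wild-diversity denominator of ROD fluctuates
  severalfold.  The suite reports the recovery rate honestly rather than
  tuning the generator to guarantee it.
* The forward engine tracks whole chromosomes as dense haplotype matrices;
  it is comfortable at desk scale (≤ tens of Mb × ≤ thousands of samples)
  but is not a substitute for specialised simulators at genome scale.
* EM-REML for the BLUP model is linear-convergent; pathological unbalanced
  designs may need more than the default 500 iterations.
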