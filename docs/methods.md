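# Methods

This note documents the statistical machinery, the defaults and why they
were chosen, what the synthetic cohorts do and do not emulate, and the
numerical conventions.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and containers

All genomic coordinates are 1-based inclusive internally (the VCF
convention); conversion to BED's 0-based half-open intervals happens only
when writing.  The `GenotypeMatrix` holds per-sample ordered allele pairs
(0 = ref, 1 = alt, −1 = missing) and a per-call phased flag taken from the
GT separator.  Only biallelic SNVs enter the pipeline; multiallelic sites
and indels are dropped at ingest with a logged count.  Minor-allele
frequency is recomputed on whatever sample subset an analysis uses; at
MAF = 0.5 the ref allele is designated major (a deterministic tie-break).
Frequency classes: common MAF ≥ 5%, low-frequency 0.5% ≤ MAF < 5%.

Missing data policy: pairwise exclusion for LD counts, per-test exclusion
in association, and samples missing (or unphased at) any target SNV are
dropped from haplotype extraction, all with logged counts.

## Pairwise LD

For a phased pair of loci the four gamete counts are read directly off
the chromosomes of samples phased and complete at both loci.  Statistics
follow the classical definitions: D = p_AB − p_A·p_B;
D′ = |D| / D_max with D_max = min(p_A·p_b, p_a·p_B) for D > 0 and
min(p_A·p_B, p_a·p_b) otherwise (D′ = 0 when D = 0); r² = D² /
(p_A·p_a·p_B·p_b).  The LOD score is the log10 multinomial likelihood
ratio of the estimated gamete frequencies against linkage equilibrium at
the same allele frequencies; it is clamped at 0 (the MLE dominates).
Monomorphic pairs are flagged `informative = False` rather than emitting
NaNs.

**Two-locus EM (unphased input).**  Only the double heterozygote is
phase-ambiguous.  The EM starts at linkage equilibrium (products of the
allele frequencies, which the genotype margins fix), splits the double
heterozygotes between the cis and trans resolutions in proportion to the
current p_AB·p_ab vs p_Ab·p_aB, and stops when the largest absolute
frequency change is below 1e−10 or after 1000 iterations.  The start and
tolerances are exposed; the per-iteration log-likelihood is
non-decreasing (asserted in tests) and the result matches a dense grid
search over the single free parameter to 1e−4.

**D′ confidence bounds.**  The gamete likelihood is evaluated on a D′
grid over [0, 1] (step 0.001) with haplotype frequencies reconstructed
from the allele-frequency MLEs and the sign of D fixed at its MLE; the
profile is normalized to unit mass and the bounds are the grid values at
cumulative mass 0.05 and 0.95.  This is the Gabriel-style construction
the confidence-interval block test needs; the upstream analyses delegated
it to Haploview, which documents no formula, so the construction and all
constants are explicit here and configurable.  One known property of the
percentile form: when the MLE sits on the boundary (D′ = 0 or 1) at small
n, the 5th/95th percentiles do not bracket it exactly; they converge to
it as n grows.

Pairs farther apart than 500 kb (configurable) are skipped when building
LD matrices.

## Block partitioning

All three methods run per population on the same marker set and emit
non-overlapping blocks of ≥ 2 markers.

* **CIT** — each pair is classed from its D′ bounds: *strong LD* iff
  ci_low ≥ 0.70 and ci_high ≥ 0.98; *recombination* iff ci_high < 0.90;
  otherwise uninformative.  A candidate block is an interval whose
  outermost pair is strong and in which strong pairs are ≥ 95% of the
  informative (strong + recombination) pairs.  Haploview's additional
  size-stratified small-block heuristics are deliberately not reproduced.
* **FGR** — a pair shows recombination iff all four gametes reach
  frequency 0.01 (from phased counts, else EM-expected); blocks are
  maximal runs with no internal recombinant pair, emitted left to right.
* **SSLD** — a block is a maximal interval whose first or last marker has
  D′ ≥ 0.80 with every other marker in it (a spine from either end).

Overlapping CIT/SSLD candidates are resolved greedily by descending
marker count, ties to the leftmost start — deterministic, and the only
free choice the published rule descriptions leave open.

**Consensus.**  Boundary *intervals* (the bp gaps between consecutive
block spans; region flanks do not count) are accumulated per base across
all partitions via an interval sweep.  Maximal runs with support ≥ 10 (of
15 for five populations × three methods) are pan-boundaries; the
complementary intervals are pan-blocks.  Support is accumulated over
intervals rather than exact coordinate identity because block edges
shift by a marker between methods while the underlying recombination gap
is shared; the profile is invariant to partition input order.

## Haplotypes

Haplotype strings over a chosen SNV set use '0' for the major and '1'
for the minor allele, read directly off phase.  Labels Hap1, Hap2, … are
assigned by descending pooled chromosome count across cohorts, ties by
lexicographic string — the all-major haplotype is *not* hard-coded to
Hap1.  Classes count minor alleles m of L: 0 → major, 1 → Q-major,
L−1 → Q-minor, L → minor, else mosaic (at L = 2 the Q-major rule takes
precedence).  Abundance per cohort: common > 5%, rare < 1%, otherwise
intermediate, on per-chromosome frequencies.

The minimal tag-SNV search is exhaustive over position subsets of
ascending size (feasible to L = 20) and reports every minimal set plus
redundancy groups: positions whose allele column — up to global
complementation — duplicates another's carry identical distinguishing
information.

Multi-phaser concordance accepts a sample iff ≥ 2 phasers agree exactly
on the unordered haplotype pair and uses the majority call; discordant
samples are removed before association.  An in-package window EM
(Excoffier–Slatkin style, uniform start over the 2^k space, tolerance
1e−8, ≤ 2000 iterations, k ≤ 12) provides a fallback phaser so the
pipeline runs without external tools; maximum-posterior diplotype ties
are broken lexicographically and flagged.

## Association

Fisher's exact test is two-sided by the probability-mass rule (the sum of
hypergeometric probabilities of tables no more likely than the one
observed, with a 1e−12 tolerance), delegated to scipy and checked in the
suite against full enumeration.  Degenerate margins give p = 1 with a
flag.  Bonferroni thresholds are α/m with m the number of tests in the
family (SNVs of a frequency class; catalog haplotypes; observed
genotypes); rounding to 3 significant figures happens only at display.

SNV tests compare allele counts (the case-matrix minor allele) between
cases and controls; when a control cohort exists only as allele
frequencies (a public panel without individual-level genotypes), counts
are reconstructed as round(freq × 2N), half-up.  Haplotype tests compare
chromosome counts (one haplotype vs all others), genotype tests compare
individual counts of each unordered pair.

**Transmission models.**  Logistic regression of status on the coded
exposure — dominant: carrier indicator; recessive: homozygote indicator;
multiplicative: copy number 0/1/2 — optionally plus a male indicator
(female reference; unknown sex excluded, logged).  Wald CI and p.  BIC is
computed as k·ln(n) − 2·lnL with n the analyzed individuals; the best
model is the lowest BIC among converged, non-separated fits.  Separation
is declared on |β| > 15 or perfect classification by exposure, in which
case no OR is reported.

## The synthetic cohorts

The generator plants exactly the structure the pipeline is meant to
find, nothing more.  Each block has a haplotype pool with per-population
frequencies; a chromosome keeps its pool index across blocks unless a
boundary recombination fires (probability `boundary_recomb` per
boundary; free re-draw), with optional within-block switching (default
0).  Disease status follows a logistic penetrance on the focal-block
diplotype: odds = baseline_odds × effect(genotype class); sampling
continues until the requested case and control quotas fill.  Sex is
simulated independently of genotype, so sex-adjusted fits can be checked
against unadjusted closed forms.  Everything is deterministic given the
seed, and the truth record carries planted boundaries, pool frequencies,
latent focal diplotypes and effects.

What this does **not** emulate: coalescent genealogies, mutation,
genotyping error, imputation uncertainty, LD decay within blocks, or
partial recombination between specific parental chromosomes.  Passing
recovery tests therefore shows the inference machinery is correct under
clean planted structure, not that it is robust to real-data noise.

Two documented scenarios:

* `default_scenario` — one population, 100 cases / 400 controls; a
  7-marker focal block whose pool holds the all-major risk haplotype at
  42%, its yin-yang complement, three mosaics and a Q-major haplotype
  (so every risk-haplotype allele is population-major and the risk
  homozygote occurs in roughly 18% of controls, the frequency regime of
  the real block); two nested-pool flanking blocks; recessive odds
  multiplier 6.28 for the risk homozygote and 0.05 for the protective
  mosaic/complement heterozygote; baseline odds 0.05.
  `recessive_scenario` keeps only the recessive effect (so the
  population recessive OR is exactly 6.28); `null_scenario` clears all
  effects and uses baseline odds 1 (prevalence is immaterial without an
  effect, and an even split fills both quotas fastest).
* `block_recovery_scenario` — five populations × 200 diploids, three
  blocks with *nested* (perfect-phylogeny) pools, free boundary
  recombination, none within blocks.  Nested pools are used because they
  are the only pools recombination-free under all three partitioning
  principles at once — any mosaic-bearing pool (like the focal disease
  pool) legitimately shows four gametes inside the block and is split by
  FGR, exactly as the disease block is split in real data.  Population
  frequency variation is a Dirichlet jitter concentrated enough to keep
  every pool haplotype common everywhere; the consensus step, not the
  generator, reconciles residual disagreement.

Because the three methods genuinely disagree inside mosaic-bearing
blocks, the end-to-end disease analysis names its focal SNV set
explicitly (as the original analyses did — the clustered GWAS hits were
chosen a priori); automatic selection of the marker-densest pan-block is
the fallback when no target list is given.

## Numerical and reporting conventions

Result tables serialize with fixed column order and 6 significant
digits; reruns with the same seed and config are byte-identical.  The
run directory receives a manifest (seed, config, config hash, artifact
list).  Thresholds display at 3 significant figures.  The genotype-level
family-wise threshold of 1.79e−3 corresponds to m = 28 tests (α/m
arithmetic is the reproducible quantity).

Problem sizes used by the recovery suites — 50 replicates for block
recovery, 200 for CI coverage, 60 for BIC selection at 600 individuals,
100 for null calibration at 900 individuals — were chosen so each check
has sharp expected behavior (binomial standard errors of a few percent)
while the whole suite stays interactive.

## Known limitations

* The D′ CI construction matches the published rule description, not any
  specific Haploview build; block edges can differ from Haploview's by
  its undocumented small-block heuristics.
* The window EM phaser is exponential in window size (k ≤ 12) and is a
  fallback, not a population-scale phaser.
* Fisher p-values on discrete tables are conservative; the null
  calibration check uses a common focal genotype at moderate cohort
  sizes where the discreteness bias is negligible.
* Frequency-only control mode inherits the rounding of published allele
  frequencies; exact integer mode is preferred when genotypes exist.
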