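# haploblocks

Clusters of GWAS hits often sit inside a single haplotype block, where
strong linkage disequilibrium (LD) makes individual SNV association
signals hard to interpret: are seven clustered hits seven signals, one
signal carried by one haplotype, or something in between?  `haploblocks`
is a pipeline for *deconvoluting* such clusters, built around the analysis
style used for cardiac-arrhythmia risk loci:

1. **Pairwise LD** — D, D′, r², the LOD score, and likelihood-based
   confidence bounds on D′, from phased gamete counts or via the two-locus
   EM on unphased genotypes.
2. **Haplotype-block partitioning** per population with the three classic
   rules — the confidence-interval test (CIT, Gabriel-style), the
   four-gamete rule (FGR) and the solid spine of LD (SSLD) — plus a
   cross-population/method **consensus**: bases whose boundary status is
   supported by ≥ 10 of the 15 (5 populations × 3 methods) partitions are
   *pan-boundaries*, the intervals between them *pan-blocks*.
3. **Haplotype cataloging** over a focal SNV set read directly off phase:
   labels `Hap1, Hap2, …` by descending pooled frequency; classes
   `major` (all major alleles), `Q-major` (all but one), `mosaic`,
   `Q-minor`, `minor`; minimal **tag-SNV (htSNV)** sets by exhaustive
   subset search; and a majority-vote concordance rule for diplotypes
   called by multiple phasers.
4. **Case-control association** at SNV, haplotype, and genotype
   (diplotype) level with two-sided Fisher exact tests and per-family
   Bonferroni thresholds (α/m), including a frequency-only control mode
   for reference panels without individual-level genotypes.
5. **Transmission models** — unconditional logistic regression of disease
   status on a focal haplotype's copy number under dominant (≥ 1 copy),
   recessive (2 copies) and multiplicative (per-copy) coding, optionally
   sex-adjusted, reported as OR with 95% Wald CI and compared by
   BIC = k·ln(n) − 2·lnL.
6. A seeded **cohort simulator** that plants block structure (per-block
   haplotype pools, recombination confined to boundaries), population
   frequency variation, and genotype-level disease effects (e.g. a
   recessive risk homozygote and a protective heterozygote pair) through a
   logistic penetrance — with a machine-readable truth record, so every
   stage of the pipeline can be scored against known ground truth.

## Worked example

Simulate the planted disease scenario (a 7-SNV focal block carrying six
common haplotypes — including a fully complementary "yin-yang" pair — a
recessive odds multiplier of 6.28 for the major-haplotype homozygote, and
a protective compound heterozygote), then run the full pipeline:

```python
import haploblocks as hb
from haploblocks.pipeline import PipelineConfig, run_pipeline

cohort = hb.simulate_cohort(hb.default_scenario(seed=1))
cfg = PipelineConfig(consensus_threshold=2, seed=1,
                     target_snvs=[f"rs_b1_m{k}" for k in range(7)])
summary = run_pipeline(cohort.genotypes, cohort.samples, cfg,
                       out_dir="run")
```

The run directory receives the LD table, per-method block BEDs, the
consensus profile, the haplotype catalog, diplotypes, the three
association tables and the transmission fits.  Headline entries of
`summary`:

```
catalog classes: {'Hap1': 'major', 'Hap2': 'minor', 'Hap3': 'mosaic',
                  'Hap4': 'Q-major', 'Hap5': 'mosaic', 'Hap6': 'mosaic'}
htSNV minimum k: 4
redundant groups: [[0, 3, 5], [1, 2]]
genotype hits: ['Hap1/Hap1']
Hap1 best model: recessive
Hap1 recessive OR: 8.44  p: 2.02e-17
```

Read: the catalog recovers the planted pool (the all-major haplotype, its
yin-yang complement, and the mosaics); 4 of the 7 SNVs suffice to tag the
common haplotypes because positions {1, 4, 6} carry one shared allele
column and {2, 3} another (1-based); the risk homozygote `Hap1/Hap1` is
the only Bonferroni-significant genotype, enriched in cases, while the
planted protective pair is depleted; and BIC picks the generating
(recessive) model, with the fitted OR's confidence interval covering the
planted 6.28.

The same stages are exposed as a CLI — `haploblocks simulate | ld |
blocks | haplotypes | assoc | transmission | run` (the `blocks`
subcommand also writes the consensus profile); see `haploblocks --help`.

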