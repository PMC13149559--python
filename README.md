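# vusplice

Tools for resolving splice-site variants of uncertain significance (VUS)
from transcriptome evidence, modelled on the analysis chain used for a
*DEGS1* 5′ splice-site variant: junction-level percent-spliced
quantification against a large background cohort, Tukey-fence outlier
splicing detection, isoform-fraction and structure/consequence analysis,
splicing-reporter PSI statistics (ANOVA + Dunnett), plasma
dihydroceramide/ceramide (DHCer/Cer) ratio analysis, and antisense
oligonucleotide (ASO) walk design. A seeded synthetic-data module
generates every input format the pipeline consumes, so the full chain is
testable without access to restricted patient or cohort data.

Intended users: genomics analysts and method developers working on
splicing outlier detection and functional follow-up of splice VUS.

## The statistics at the core

**Percent-spliced (PS).** For a splice junction *j* (an intron interval)
in sample *s*,

    PS(j, s) = n(j, s) / ( n(j, s) + Σ_{j′ ∈ E(j)} n(j′, s) )

where *n* is the junction-spanning read count and the exclusion set
*E(j)* contains every other junction whose intron interval overlaps
*j*'s (half-open semantics; a shared boundary is not overlap). PS is
undefined when the denominator is zero.

**Outlier splicing.** Per junction, cohort PS values give quartiles Q1
and Q3 and IQR = Q3 − Q1. A query PS is an up-outlier when
PS > Q3 + 1.5·IQR and a down-outlier when PS < Q1 − 1.5·IQR (strict
inequalities).

**Isoform analysis.** Per-gene isoform fractions are TPM_i / Σ TPM;
candidate transcripts are classified against the canonical model by
intron-chain comparison (exon skipping, altered splice site, other), and
protein consequences are predicted by translating the candidate from the
canonical start codon and diffing peptides into HGVS p. notation
(`p.(=)`, `p.X10_Y19del`, `p.Ala28Glyfs*7`-style frameshifts).

**Reporter PSI.** PSI = 100·inc/(inc+skip) from fragment-analysis peak
signals, compared across conditions by one-way ANOVA and Dunnett's
many-to-one test with Monte-Carlo max-|t| adjustment.

**Lipid readout.** Per acyl chain, the DHCer/Cer ratio (replicate-mean
concentrations) is expressed as fold over the control-group mean and
tested proband-vs-control with a pooled two-tailed Student's t test.

## Worked example

Simulate a 100-sample background cohort (mean exon-2 skip fraction 2%)
plus a patient whose exon-1-3 skip junction carries 56% of junction
usage, then call outliers:

```python
from vusplice import (
    CohortSimConfig, simulate_junction_cohort, build_exclusion_sets,
    percent_spliced, build_background, call_outliers,
)

cfg = CohortSimConfig(seed=11, n_background=100, depth_mean=5000)
background, patient = simulate_junction_cohort(cfg)
excl = build_exclusion_sets(background.junctions)
cohort_ps = percent_spliced(background, excl)
patient_ps = percent_spliced(patient, excl)
bg = build_background(cohort_ps, min_samples=20)
for c in call_outliers(patient_ps.sample_column("patient"), bg, "patient"):
    print(f"{c.junction.name}  PS={c.ps:.3f}  "
          f"fences=({c.lower_fence:.3f}, {c.upper_fence:.3f})  -> {c.direction}")
```

prints

```
chr1:1100-1200:+  PS=0.291  fences=(0.855, 1.067)  -> down
chr1:1300-1400:+  PS=0.274  fences=(0.850, 1.070)  -> down
chr1:1100-1400:+  PS=0.559  fences=(-0.036, 0.076)  -> up
```

The two inclusion junctions (exon 1-2, exon 2-3) fall far below their
cohort fences while the exon-1-3 skip junction — at PS 0.559, against a
background upper fence of 0.076 — is a clear up-outlier: the signature
of a variant that forces exon 2 skipping.

The same pipeline is available from the shell:

```sh
vusplice run --seed 11 --out results/         # simulate + all stages
vusplice outliers --sj-dir sj/ --query patient --min-samples 20
vusplice reporter --peaks peaks.csv --control reference
vusplice lipids --panel panel.csv
vusplice aso --target exon2.fa --k 18 --step 1
```

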