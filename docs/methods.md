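# Methods

## Percent-spliced quantification

Junctions are stored as 0-based half-open intron intervals; the STAR
`SJ.out.tab` dialect (1-based inclusive) is converted at the parser
boundary, and only unique-mapping read counts are used by default
(`include_multimappers=True` adds the multi-mapper column; whether
upstream junction quantifiers count multi-mappers or apply overhang
filters varies, so both behaviours are exposed rather than one claimed
canonical).

The exclusion set of a junction contains every other junction on the
same contig with a compatible strand whose intron interval intersects
with nonzero length. Two deliberate edge rules: junctions sharing only a
boundary coordinate do **not** overlap (half-open semantics — a shared
splice site is a shared exon edge, not a mutually exclusive outcome),
and strand compatibility treats unknown strand (`.`) as matching both
explicit strands, while `+` never excludes `−`. PS is count over
(count + exclusion counts), undefined (NaN, never 0) when the
denominator is zero.

## Outlier calling

Cohort PS distributions are summarised per junction by Q1/Q3 and Tukey
fences at 1.5·IQR. The quantile rule matters for small cohorts and is
configurable: `linear` (interpolated order statistics, the scientific
default), `tukey_hinges` (median-of-halves), or `nearest`. Comparisons
with the fences are strict (`>` / `<`), so a query sitting exactly on a
fence — including the degenerate zero-IQR case where both fences equal
the constant background value — is not an outlier.

Missing background PS values are dropped, not imputed as zero, on the
view that an unobserved junction says nothing about its usage ratio;
`missing_as_zero=True` implements the alternative convention (a junction
that attracted no reads was not used). Junctions with fewer than
`min_samples` (default 20) usable values are flagged `not_evaluable`
rather than summarised from noise. The query sample must not be part of
the background cohort; this is checked by sample id.

## Isoform structure and consequence

Transcripts are compared by intron chain, not exon endpoints, so
terminal-exon length differences do not change the category. Exon
skipping is detected as a candidate chain obtainable by merging runs of
consecutive canonical introns (each merge spans whole skipped exons);
skipped-exon ordinals are reported in transcript (5′→3′) order, which on
the minus strand differs from genomic order. A single moved intron
boundary is `altered_splice_site`; anything else is `other`.

Protein consequences splice the candidate's exonic sequence, locate the
canonical start codon genomically, and translate both frames to the
first stop (standard genetic code, no selenocysteine). Peptide diffs are
normalised as follows: a clean contiguous deletion with preserved frame
and flanks is reported 3′-most (longest common prefix first), e.g.
`p.Pro5_Pro7del`; a divergence with downstream frame change is
`p.<Ref><pos><Alt>fs*<n>` with the first changed residue counted as 1
and *n* pointing at the new stop (`fs*?` if no stop is reached before
the transcript ends); loss of the start codon is `start_lost`; stop
gain/loss and junction delins fall into `other`. In-frame deletions are
reported without further 3′-rule shifting across repeated flanking
residues beyond the prefix-maximisation above, so byte-identity with
other annotators' strings is not guaranteed for repeat-containing
proteins.

A real-data integration example (not a unit test, since it needs the
external RefSeq sequence): splicing exon 2 out of the three-exon *DEGS1*
reference transcript NM_003676.4 produces the frameshift
NP_003667.1:Ala28Glyfs*7, and the cryptic-acceptor isoform an in-frame
deletion of the Thr195–Val276 transmembrane region.

## Reporter PSI and Dunnett statistics

Peaks are assigned to the expected included/skipped amplicon sizes by
nearest distance within ±5 nt (fragment analyzers drift; tolerance
configurable, windows must not overlap). Signals are used as-is — no
molar/size correction is applied by default because the quantification
protocol this emulates reports none; the correction hook exists but is
off. PSI is reported on the 0–100 scale.

The one-way ANOVA is the classical sum-of-squares F test with explicit
degenerate handling (all-constant data → F = 0, p = 1, flagged).
Dunnett's many-to-one comparisons use the variance pooled across all
groups; the family-wise adjustment is Monte-Carlo: the joint null
max-|t| distribution is sampled (shared control mean, shared chi-square
variance factor, default 10⁵ seeded draws), and the adjusted p is the
add-one exceedance estimate (k+1)/(n+1), clipped from below by the
unadjusted per-comparison p so single-step coherence holds exactly under
MC noise. This removes any dependence on critical-value tables and
handles unbalanced designs; reps and seed are recorded in every result.
With a single treatment group the procedure reduces to the pooled
two-sample t test (verified to ±0.005 at 10⁵ reps in the test suite).

## Lipid ratio analysis

Technical replicates are averaged within each (sample, species) before
any between-group statistic — the unit of analysis is the biological
sample, avoiding pseudo-replication. Ratios are DHCer/Cer per acyl
chain; zero or missing denominators are flagged, never dropped
silently. Folds are relative to the control-group mean ratio (controls
average 1 by construction) and are invariant to global concentration
rescaling. The group test is the pooled Student's t (two-tailed,
α = 0.05) to match the convention this analysis follows; Welch is
available as an option, and the test can be run on ratios (default) or
on raw DHCer concentrations, each labelled in the output. No
multiple-testing correction is applied across lipid species, and the
report notes this.

## ASO walk design

Windows of length *k* (default 18 nt) tile the target at a configurable
stride (default 1 — a dense walk maximises coverage and the caller can
thin). Each ASO is the reverse complement of its window, emitted in the
DNA alphabet (U pairs as A), annotated per-position 2′MOE sugar on a
phosphorothioate backbone. Windows containing N are emitted flagged.
Off-target search, melting temperature, and efficacy prediction are out
of scope.

## Synthetic-data generators

The generators reproduce the statistical structure the analysis assumes,
at the scale of the study they emulate:

- **Junction cohort** — 670 background samples by default, a three-exon
  gene with junctions e1-e2, e2-e3 and the e1-e3 skip. Per-sample
  junction-spanning depth is negative binomial (mean 2000, dispersion
  10 — depth and dispersion for the emulated cohort are not published,
  so these are plausible placeholders, exposed in config and not
  calibrated); the skip fraction ψ is Beta-distributed across background
  samples (mean 0.02, concentration 50) and fixed at 0.56 for the
  patient; skip reads are Binomial(N, ψ) and the remainder is split
  multinomially across the inclusion junctions. The expected PS of the
  skip junction is ψ, which the tests verify by Monte-Carlo.
- **Abundance tables** — TPM_i = total·fraction_i·lognormal(cv); the
  default fractions (6/69/12/13%) are the patient isoform profile.
- **Reporter runs** — nine replicates; included/skipped peak signals
  proportional to ψ and 1−ψ under mean-1 log-normal noise (CV 0.1);
  zero-weight peaks are omitted, so complete skipping yields
  skipped-only electropherograms.
- **Lipid panels** — 9 controls vs 2 probands, technical triplicates,
  log-normal noise (CV 0.1). The per-chain ratio fold F (default 42, the
  low end of the effect range this emulates) is realised symmetrically:
  proband DHCer means ×√F, Cer means ÷√F, making the configured ratio
  fold exact in the no-noise limit.

All noise is multiplicative log-normal parameterised by its CV (positive
support; degenerate at cv = 0), and every generator is bit-reproducible
given its seed. What the simulations do **not** model: read-level
artefacts (mappability, overhang filters, multi-mapping), correlated
junction usage across a real transcriptome, batch structure in cohorts,
peak-shape/stutter artefacts in fragment analysis, and lipid species
correlations. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated generative assumptions, not
robustness to those real-data complications.

## Problem sizes in the test and acceptance runs

Replicate loops use cohorts of 100 samples (the package handles the full
670-sample default in one pass), 100-replicate outlier-recovery runs at
depth 5000, 200–500 reporter simulations per PSI level, 200 lipid
panels, and 500–1000 null experiments for the Dunnett family-wise error
check at 10⁴ MC reps each — sizes chosen so the whole suite completes in
well under a minute while keeping Monte-Carlo standard errors an order
of magnitude below the tolerances being asserted.

## Known limitations

- The exclusion-set scan is quadratic per contig in the worst case;
  fine for gene-level junction sets, not tuned for transcriptome-wide
  matrices.
- HGVS strings cover the consequence classes reachable by exon skipping
  and splice-site shifts; they are not a general-purpose HGVS engine
  (no delins normalisation, no extension termini).
- The Dunnett adjustment is single-step (max-|t|), not step-down.
- PS treats junction counts as independent evidence; no attempt is made
  to model shared reads between overlapping junctions.
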