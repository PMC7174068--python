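# Methods

This note documents the models, estimators and simulation choices behind
`tmbcompare`, including the places where a design decision was genuinely
open and what the synthetic cohorts do and do not demonstrate about real
data.

## TMB definition and footprints

TMB is computed as `variant_count / footprint_mb` at full floating
precision; any rounding happens only in report output, so samples near
clinical cut-offs are never reclassified by formatting.

Two footprint constructions are deliberately asymmetric:

- **Panel footprint** — for each panel gene, the *longest transcript*
  (by coding length; ties broken by lexicographically smallest transcript
  id so footprints are reproducible) contributes its coding exons; exons
  are merged per chromosome, so coding sequence shared by two panel genes
  is counted once.  "Longest" means longest *coding* sequence, consistent
  with a coding-variant numerator.
- **Exome footprint** — the union of *all* coding exons of *all*
  transcripts of all genes, merged.  This mirrors how exome capture tiles
  every annotated coding exon rather than one representative transcript.

Coordinates are 1-based inclusive at the GTF boundary and 0-based
half-open internally; all interval arithmetic happens in the internal
convention.  Gene symbols are matched case-sensitively after whitespace
trimming, with no alias resolution.  Panel genes missing from the
annotation are reported as a warning and excluded; only a fully missing
panel is an error.

## Variant inclusion

A counting method is an `InclusionPolicy`: allowed variant classes (SNV,
insertion, deletion), a synonymous toggle, and a region (footprint).  The
region test uses the variant's leftmost affected reference base (the VCF
anchor base for indels).  Consequences `noncoding` and `unknown` never
count — TMB counts variants *within coding exons* — and annotated splice
variants count as non-synonymous coding events by default (configurable,
since assay practice varies).  Records failing VCF FILTER are dropped and
counted; exact duplicate events within a sample are collapsed and counted.
No minimum-VAF filter is applied: allele-fraction thresholds belong to the
upstream variant caller, whose output lists are this package's input.

Single-base codon substitutions are classified against the standard
genetic code (synonymous / missense / nonsense).  Under uniform sense
codons, uniform positions and uniform alternate bases the synonymous
probability is exactly 134/549 ≈ 0.2441 — the code-determined constant
that makes the all-coding vs non-synonymous regression slope
1/(1−0.2441) ≈ 1.323.

## Concordance statistics

Deming regression treats both TMB measurements as noisy; the closed-form
slope (see README) uses the error-variance ratio λ = var_y/var_x, default
1 (orthogonal regression) and exposed as a flag, since the ratio used by
any given published comparison is rarely recoverable.  Slope confidence
intervals use a leave-one-out jackknife with a normal approximation,
computed from down-dated moment sums in O(n).  No weighting and no outlier
exclusion are applied; zero-inflated TMB vectors are retained, and only
exact degeneracy (constant x, zero covariance) aborts a fit — inside the
all-pairs comparison grid such failures are flagged per cell rather than
aborting the grid.  Bland–Altman agreement reports mean bias of y−x with
1.96·SD limits (sample SD, n−1).

The magnitude of the synonymous-toggle bias in absolute units depends on
the cohort's rate distribution (bias = 0.32 × mean non-synonymous TMB of
the subset considered), so tests assert the structural identities rather
than a cohort-specific band.

## Survival analysis

Quartile cuts are empirical 25/50/75 percentiles with linear interpolation
between order statistics (recorded in the output, because membership near
a cut depends on the quantile definition); ties at a cut fall into the
lower quartile.  Strata with fewer than 8 samples are skipped with a
warning; a stratum with constant TMB admits only one group and is an
error pan-cohort (skipped with a recorded reason within tumor types).

Kaplan–Meier curves come from lifelines.  The Cox model is unadjusted with
quartile as a categorical covariate, fit by statsmodels' PHReg partial
likelihood with Efron tie handling by default (Breslow available).  The
model is fit once; contrasts against any reference quartile are derived by
exact linear transformation of the coefficient vector and covariance, so
re-referencing inverts hazard ratios to machine precision.  A group with
no events produces a monotone likelihood; such groups are flagged (HR 0,
infinite upper bound) and excluded from the fit instead of aborting.  TMB
and clinical tables are inner-joined on sample id with mismatches logged,
never imputed.  No multiple-testing correction is applied across tumor
types — per-stratum HRs are reported with their own CIs only.

## Synthetic cohorts

The generator produces complete study inputs (GTF, panel gene lists, one
VCF per tumor, clinical TSV) that are byte-identical under a fixed seed.
What it emulates, per sample: a tumor type; a per-Mb mutation rate drawn
log-uniformly within that type's range (defaults span 0.5–100/Mb across
five types, giving per-tumor counts over several orders of magnitude);
Poisson variant counts per gene proportional to the gene's coding
footprint, optionally scaled by per-panel rate multipliers (how
"panels sampling atypically mutating regions" is produced); uniform
placement within coding exons; consequences either mechanistic
(`genetic_code`: random sense codon, position and substitution — the ~25%
synonymous fraction *emerges*) or `fixed_fraction` for sharp targeted
tests; indels at a configurable fraction (default 0.1, 1–6 bp, frameshift
when the length is not a multiple of 3).  Survival times are exponential
with hazard h₀·exp(β·log(TMB+1)) driven by the sample's *true* simulated
rate (so no counting method is privileged), with independent exponential
censoring whose rate is solved numerically to hit the configured expected
censoring fraction (default 0.55).

Genes (default 20,000) have log-normal coding lengths (mean 1.5 kb,
log-SD 0.6, floored at 150 bp and rounded to whole codons), 1–20 exons,
and 1–3 transcripts in which shorter transcripts are exon prefixes of the
longest — so a gene's coding union equals its longest transcript, keeping
the per-base mutation density exactly uniform across footprint
definitions.  Panels are drawn from a shared 800-gene pool, reflecting the
substantial overlap of real clinical panels' core cancer genes.

Not modeled (out of scope by design): sequencing reads and depth, calling
error, trinucleotide mutational signatures, tumor purity and subclonality,
germline contamination, covariate-adjusted survival.  Passing tests on
these cohorts therefore demonstrate the *informatics* pipeline —
footprint arithmetic, counting policies, estimator correctness and the
structural consequences of panel size and synonymous counting — not
fidelity to any particular tumor type's empirical TMB distribution, whose
generator defaults are order-of-magnitude placeholders.

## Experiment problem sizes

The pre-registered experiments (`tmbcompare.experiments`) use: 500 tumors
and a 4,000-gene exome for the synonymous-toggle regression (the exome
size only sets the denominator and does not affect slope or correlation);
500 tumors and the full 20,000-gene exome for panel concordance; 500
tumors and an 8,000-gene exome for multiplier recovery; 400 tumors for the
cross-method hazard-ratio direction check; and 200 replicates of 800
subjects for Cox CI coverage.  These sizes keep every experiment within
seconds to about a minute on one core while leaving Monte-Carlo error
well inside the asserted tolerances, with one knife-edge exception: under
the prescribed uniform-rate cohort the population panel-vs-WES Pearson
correlation is ≈0.970, so a sharp ≥0.97 assertion sits exactly at the
expectation and can land on either side for a given seed (the seed-to-seed
SD of the estimate is ≈0.003).  The estimate itself, not the threshold, is
what the reproduction script reports.

## Numerical notes

- Deming jackknife uses down-dated (leave-one-out) moment formulas; leave-
  one-out slopes that are non-finite (degenerate subsets) are dropped from
  the SE.
- The brute-force Deming oracle used in tests minimizes the orthogonal
  weighted residual over the line's *angle*, which keeps the comparison
  uniformly stringent across slope magnitudes; near-degenerate instances
  have objectives flat to ~1e-12 where no float64 search can localize the
  minimizer more precisely.
- Percentile and interval operations use numpy; membership tests use
  searchsorted over merged interval arrays (vectorized per chromosome in
  the cohort TMB path, and cross-checked against the per-record path in
  tests).
- VCF/GTF/clinical writers emit plain text deterministically (sorted
  records, fixed formatting); parsing uses pysam and gffutils.
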