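# Methods

## The screen model

The package scores variants from a pooled re-expression proliferation
screen. A codon-level variant library of a tumor-suppressor ORF is
introduced into suppressor-deficient cells; re-expressing a *functional*
variant slows proliferation, so functional variants deplete and
loss-of-function (LOF) variants enrich over the competition. Abundances
are read out by deep sequencing at an early timepoint (shortly after
transduction) and a late timepoint (after 8–14 days of growth), in several
replicate cell contexts with distinct modes of suppressor deficiency.

Input counts are taken as given (upstream variant calling from reads, e.g.
GATK AnalyzeSaturationMutagenesis, is out of scope).

## Functional z-score

Per replicate, counts are converted to relative frequencies with a
pseudocount (default 0.5 per variant) and the variant's abundance change is
`L2FC = log2(f_late / f_early)`. Each L2FC is standardized against the
rolling silent baseline: the sample mean and SD (n−1 denominator
throughout) of silent-variant L2FC within ±2 codons of the variant's
residue. The per-replicate z-scores are averaged into the final score; the
across-replicate SD is reported as a consistency measure.

Numerical choices, all configurable:

- **Pseudocount 0.5, per-sample frequency normalization.** The upstream
  normalization is a free choice of the pipeline; 0.5 is the common
  pooled-screen convention. With pseudocount 0 the z-scores are exactly
  invariant to per-sample depth scaling; with 0.5 the residual effect is
  O(pc/count).
- **Window half-width 2, `min_silent` 3.** Windows are truncated at the ORF
  ends (physical neighbors only, never mirrored) and expand symmetrically
  one codon at a time until at least 3 silents are captured, so every
  residue has a baseline even where synonymous codons are absent. An SD
  from fewer than 3 points is too unstable to divide by.
- **Focal silent inclusion.** A silent variant contributes to its own
  window by default (the window is defined by position, not identity); a
  leave-one-out mode exists for diagnostics.
- **SD floor.** A window whose silents are identical (SD 0, or n < 2 after
  covering the whole ORF) would give infinite z; such windows fall back to
  the replicate-wide silent SD and are flagged `sd_floored`. A replicate
  whose silent L2FCs have zero spread overall is unusable and raises.
- **Degenerate inputs.** All-zero count columns with pseudocount 0,
  missing early/late samples, duplicate variant ids, and libraries without
  silent variants are rejected with explicit errors.

The scorer is exposed as a sklearn-style transformer (`FunctionalScorer`,
with `fit`/`transform`, `get_params`, and fitted attributes `l2fc_`,
`baseline_`, `scores_`), so it composes with sklearn tooling; module
functions implement the individual steps for direct use.

## Classification

- LOF call: strict `mean_z > 2` (two silent-baseline SDs of enrichment).
- Residue intolerance: the mean of available missense `mean_z` per residue
  (up to 19 substitutions; only missense enters the average). The cutoff
  is mean + 2·SD of the residue averages, recomputed from the supplied
  score set; residues with fewer than 10 scored substitutions are excluded
  from the cutoff estimate by default (both modes are available, since a
  sparse residue average is noisy enough to distort the spread estimate).
  Flags use strict `>` at both thresholds.
- Positional profiles: per-position class means with a centered moving
  average (half-width 5, truncated at the ends), plus a variant-effect-map
  matrix export (20 amino acids + stop + frameshift + residue-average rows).

## Library model

Consequences follow the standard genetic code (via Biopython's table).
The enumerated library uses one codon per target amino acid for missense
(the most-used human codon; 19 entries per residue), all synonymous codons
for silent entries (a denser neutral baseline), one nonsense allele per
position (a stop reachable by one nucleotide substitution when one exists,
else TGA), and one single-base-deletion frameshift per position. Variant
ids follow the field convention (`R377H`, `R377*`, `fs377-1`); silent ids
append the codon (`K2K.AAG`) since several synonymous codons can encode the
same residue. Protein-level variants expand to the SNVs that encode them,
which is how codon-level scores join SNV-level predictor tables; an SNV is
matched at the (position, alt-amino-acid) level, with exact alternate-codon
match breaking ties among synonymous entries.

## Predictor benchmarking

Predictor thresholds are inclusive (≥), at the tools' published stringent
cutoffs: CADD PHRED 20, AlphaMissense 0.56, REVEL 0.78. Concordance calls
a record concordant when the DMS class (LOF iff mean z > 2, the single
rule for every consequence class) agrees with the predictor class. AUC is
the tie-corrected midrank Mann–Whitney statistic; curve points come from a
threshold sweep (scikit-learn). The Fisher exact test for the quadrant
statistic is an exact integer hypergeometric enumeration with the standard
two-sided "probability mass ≤ observed" rule; the quadrant null is
operationalized as independence of the two sign margins in a 2×2 table,
the only construction under which the exact test is defined (skewed but
independent margins are deliberately not penalized).

## The synthetic generator

`simulate_screen` draws initial abundances from a log-normal with
σ = 0.5 (library representation skew), applies selection as
`w^d · 2^(b(p))` with fitness `w = (1 − s_r)^activity` (activity 1 for
functional, 0 for LOF, intermediate for partial alleles), multiplies by
mean-1 gamma noise (shape 20, ~22% CV, the overdispersion beyond counting
noise typical of pooled screens), and samples early/late counts
multinomially at depth 5×10⁵. All randomness flows from a single seeded
generator; regeneration is bit-identical per seed.

Default study conditions: 120-residue ORF (~2,900 variants; a full-length
385-residue screen is a config change), 3 replicate contexts, s = 0.3,
d = 6, 1.5% of missense LOF, truncations LOF. Optional features: planted
intolerant residue intervals (all missense LOF), partial-activity
N-terminal nonsense alleles (translation re-initiation) and C-terminal
truncations (dispensable tail), and a sinusoidal positional bias
`b(p) = A·sin(2πp/L)` on log2 growth. Replicate heterogeneity spaces the
replicate-specific suppression evenly across ±20% of s — deterministic
spacing rather than random draws, so heterogeneity is modelled while the
across-replicate mean effect stays pinned to the configured s and the
closed-form L2FC separation `d·log2(1/(1−s))` remains the exact target of
the 3-replicate average.

What the generator does *not* emulate: PCR jackpotting and chimeras, tile
boundary artifacts, codon-specific translation effects, replicate-specific
depth differences, cell-line-specific transcriptional programs. Passing
recovery tests therefore demonstrates the statistics are correct under a
clean overdispersed-count model, not that every real-screen artifact is
handled.

### A note on the global-baseline ablation

A `baseline_mode="global"` ablation replaces the rolling window with the
replicate-wide silent mean/SD. Under a mean-zero sinusoidal positional
bias of amplitude A, this ablation *mis-centers* scores position-dependently
(silent variants near the bias peak acquire systematically positive z, as
the test suite demonstrates), but it cannot inflate the one-sided
`z > 2` call rate: the bias contributes A²/2 to the global silent
variance, so the largest bias-driven |z| is A / √(A²/2 + σ²) ≤ √2 < 2 at
any amplitude and noise level. The window's measurable benefit under this
bias model is calibration (correct per-position centering and near-unit
silent-z SD), not one-sided false-positive control, which the inflated
global SD incidentally preserves.

## Problem sizes

Test and acceptance runs use the 120-residue desk-scale default, chosen so
the whole suite (including 20 null screens and 10 recovery screens at
depth 5×10⁵) completes in well under a minute while every window statistic
still exercises expansion, truncation, and flooring paths.

## Known limitations

- The enumerated library is an emulation: real saturation-mutagenesis
  libraries have tile-specific codon compositions that are not public.
- Frameshift alleles are modelled as single-base deletions at the codon's
  first base; real indel structure varies.
- Reported deposited-screen statistics (LOF counts, intolerance cutoffs on
  real data) require the original count data and are outside the synthetic
  acceptance surface.
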