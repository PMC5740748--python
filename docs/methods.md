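# Methods

This note documents the scientific and numerical conventions of
`methpat`: what is computed, with which exact formulas and parameters,
and why.

## Per-molecule methylation patterns

A *methylation pattern* is the joint state of a contiguous stretch of
CpGs on one sequenced DNA molecule, written as a binary string
(`1` = methylated, `0` = unmethylated). The unit of counting is the
*fragment* (a merged read pair), not the read: mate overlaps are merged
and positions where mates disagree become AMBIG. AMBIG is a first-class
state and is always *excluded, never imputed* — a molecule with an
ambiguous call at a relevant CpG contributes to neither numerator nor
denominator.

Coordinates are 0-based half-open throughout; a CpG is identified by
its forward-strand C position, and calls made at the G of a
reverse-strand alignment are collapsed to C−1. The SAM importer reads
the Bismark methylation-call tag (`Z`/`z` for methylated/unmethylated
CpG context) and uses the bisulfite-strand tag (`XG`) to decide the
collapse, falling back to the alignment's reverse flag when absent.

Two counting semantics exist, matching their use:

* **Discovery counting** (`count_patterns`): each fragment contributes
  exactly one observed pattern — its full call vector over the covered
  contiguous CpG stretch of the window. Fragments with any AMBIG over
  covered window CpGs, or covering a non-contiguous CpG subset, are
  dropped entirely. "Covering" for a pattern counts fragments whose
  stretch spans all of that pattern's CpGs.
* **Serum quantification** (`quantify_marker`): only the *target
  pattern's own CpGs* matter. A fragment covers the marker if it has
  unambiguous calls at all target CpGs (states elsewhere are
  irrelevant), and supports it if those calls match exactly. Pattern
  frequency = supporting / covering.

Both are verified against independent brute-force string-scan oracles
on randomized fixtures (up to 10⁴ fragments).

## Discovery cascade (tissue phase)

1. **Read bundles** — maximal genomic intervals where fragments form a
   connected overlap chain of at least 10 fragments.
2. **Windows** — maximal runs of ≥ 4 CpGs whose span, measured
   inclusive of the final CpG dinucleotide (last C + 2 − first C), is
   ≤ 150 bp. Nested runs are suppressed. The dinucleotide-inclusive
   measure is what makes a 7-CpG region with offsets 0…134 span exactly
   136 bp.
3. **Pooling** — supporting/covering counts are summed across samples
   of a group (tumor, WBC), i.e. read-weighted pooling, so deeply
   sequenced samples count proportionally.
4. **Specificity score** — Sp = (c_T/N_T) / ((c_B+1)/(N_B+1)), the
   pooled tumor frequency over the add-one-smoothed background
   frequency. The +1 smoothing keeps Sp finite when a pattern never
   occurs in the background, while still rewarding deeper background
   coverage (more evidence of true absence).
5. **Filter cascade** — a candidate survives only if: Sp ≥ 10; zero
   occurrences in pooled WBC reads; ≥ 4 CpGs; ≤ 150 bp; pooled tumor
   frequency ≥ 0.05; observed in ≥ 2 tumor samples; and no surviving
   longer pattern contains it (nested-pattern suppression — the longer,
   more specific pattern is kept). Every candidate carries per-filter
   pass/fail flags; survivors are ranked by descending Sp, then
   descending tumor frequency.

Crucially, pooled totals count *every* sample's fragments against
*every* candidate pattern, including samples in which the pattern was
never observed — otherwise the background denominator degenerates and
the score loses its meaning.

## Serum panel

The shipped panel consists of markers #141, #204 and #228 with three
named threshold presets:

| preset    | #141    | #204    | #228      | setting |
|-----------|---------|---------|-----------|---------|
| `sets12`  | 0.0008  | 0.0001  | 0.0001    | development serum sets |
| `refined` | 0.0008  | 0.00003 | 0.00001   | refined final cut-offs |
| `ukctocs` | 0.00027 | 0.00001 | 0.0000033 | screening-trial sera |

A sample is **positive** if at least one *valid* marker's frequency is
strictly above its cut-off; invalid markers (zero covering reads) are
ignored; a sample with no valid marker is **not evaluable**. Coverage
below 100,000 molecules sets a QC flag but never excludes a sample.

`scale_threshold_set` divides each cut-off by a factor and rounds to
2 significant digits; dividing `refined` by 3 reproduces `ukctocs`
exactly, the compensation for ~3-fold dilution of tumor signal by
white-blood-cell DNA leaking into serum when separation is delayed.

## Evaluation statistics

* **Proportion CIs** — the continuity-corrected score ("efficient
  score" / Wilson) interval with z = 1.959964 at 95%; the lower bound
  is clamped to 0 at k = 0 and the upper to 1 at k = n. This interval
  reproduces, digit for digit, five of the six reference
  sensitivity/specificity CIs; the sixth (28/48, lower bound 43.275%)
  differs only in the final rounding convention (43.3 when rounding
  half away from zero vs. a printed 43.2), i.e. within one unit of the
  last printed digit.
* **Fisher's exact test** — two-sided by the probability-mass
  convention: the sum of all hypergeometric outcome probabilities not
  exceeding the observed one, with a 1 + 10⁻⁷ relative tolerance on
  the comparison to absorb floating-point ties. Degenerate margins
  give p = 1. Verified exhaustively against rational-arithmetic
  enumeration for all 2×2 tables with N ≤ 30 and against an
  independent library implementation on random tables.
* **Mann-Whitney U** — exact null distribution when both groups have
  n ≤ 8 and there are no ties, otherwise the normal approximation with
  continuity and tie correction.
* **CA125** — positive strictly above 35 IU/mL; overlap with the DNA
  panel is reported as truth × CA125-status × panel-status counts.
* **Chemotherapy-response prediction** — a patient whose panel call
  goes positive → negative from the pre-treatment sample to the
  post-cycle-2 sample is predicted a responder; any pattern ending
  positive predicts a non-responder; a patient with neither sample
  positive (or a not-evaluable sample) is not evaluable. Accuracy is
  reported separately for responders and non-responders, overall and
  in the no-macroscopic-residual (R0/1) subset, with a Fisher exact
  p-value on the prediction × outcome table.

## Synthetic-cohort generator

The generator exists to validate the pipeline's machinery — recovery
of planted markers, estimator calibration, monotone dose-response —
not to imitate any real cohort's exact numbers.

**Serum model.** A sample of group g draws a tumor fraction φ from a
group-specific log-normal (high-grade serous median 1.25 × 10⁻⁴,
σ = 1.5; non-shedding groups φ = 0). The expected target-pattern
frequency over a K-CpG marker is

q = (φ/λ)·m + (1 − φ/λ)·εᴷ

with m = 0.8 the fraction of tumor molecules carrying the full
pattern, ε = 0.003 the per-CpG background methylation rate, and
λ ≥ 1 a leakage/dilution factor. Covering reads are Poisson with mean
C = 100,000; supporting reads are Binomial(covering, q); a marker
fails entirely (covering 0) with probability 0.01. Inverting the
model, φ̂ = (freq − εᴷ)/(m − εᴷ) recovers φ/λ; at φ·m = 10⁻³ and
C = 10⁵ the mean relative error over 200 replicates is ≈ 8%. With
ε = 0.003 and K ≥ 5, εᴷ ≤ 2.4 × 10⁻¹³ — far below every shipped
cut-off, which is exactly why fully methylated multi-CpG patterns work
as markers.

**Tissue model.** Planted marker regions receive, in tumor samples, a
fraction m of fully methylated molecules; all other molecules (and all
null regions and WBC samples) follow independent per-CpG noise at rate
ε. Fragments cover the full region or a random contiguous CpG
sub-stretch (rate 0.2). Defaults: 6 tumor + 6 WBC samples, 3 planted
regions among 50 null regions, ≈ 200 fragments per region.

**Cohort presets.** `set3_like` (20 healthy / 20 benign mass / 20
high-grade serous, λ = 1) models a prospective diagnostic setting;
`ukctocs_like` (30 controls / 15 cases) models a screening trial with
delayed serum separation: λ = 3, DNA concentration inflated threefold
(log-normal median 20 ng/mL × λ) and the apoptotic small-fragment
fraction reduced to a mean of 0.199. `nact_like` generates
three-timepoint chemotherapy series where responders' tumor fraction
decays as φ_t = φ₀ · 0.05ᵗ (non-responders keep φ₀) and CA125 decays
more slowly (factor 0.5), reflecting its longer half-life. CA125 is
log-normal per group, calibrated so that P(CA125 > 35) ≈ 0.83 in
high-grade serous cases and ≈ 0.13 in healthy controls.

**Determinism.** Every stochastic quantity draws from its own named
stream: a seed sequence built from the user seed plus a CRC-32 hash of
a string key path (e.g. `("serum-sample", sample_id)`). Identical
seeds reproduce byte-identical outputs, and adding or reordering
samples does not disturb other samples' draws.

## Design decisions and limitations

* Standard numerics are delegated: the hypergeometric pmf and
  Mann-Whitney machinery come from scipy, SAM decoding from pysam; the
  pattern-counting primitives, the score interval, the two-sided
  Fisher summation convention and the panel logic are implemented here
  because their exact conventions are the point.
* Pipeline stages communicate through plain-text files (sample-sheet
  CSV, read-call TSV, region table TSV, quantification TSV, panel-call
  CSV), so each stage can be re-run, replaced or inspected in
  isolation; every run writes a manifest with parameters and package
  version.
* The generator makes no attempt to model amplicon/primer artifacts,
  bisulfite conversion failure, fragment-length distributions beyond a
  single small-fragment summary, or correlated CpG noise by default
  (a neighbour-copy correlation parameter exists but defaults to 0).
  Real-cohort sensitivities/specificities are therefore not
  reproduced — only printed-count statistics (which are pure functions
  of published tables) and generator-based properties are asserted.
* Exact boundary ties at the threshold ("strictly above") and at
  CA125 = 35 follow the strict reading; at 10⁵-read denominators
  boundary ties are vanishingly rare, so the choice is inert in
  practice but kept explicit.
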