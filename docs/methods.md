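# Methods

This note documents the models, conventions, and design choices behind
`woundage`, and what its synthetic validation does and does not establish.

## Study design emulated

A balanced one-way design: one control group plus 12 contusion time points
(4 h to 48 h in 4-h steps), n = 6 animals per group (78 animals), a
28-gene candidate panel split into six subgroups by ARE status and GO
category (ARE-CC 6, ARE-BP 5, ARE-MF 5, ARE+CC 4, ARE+BP 4, ARE+MF 4),
and two reference genes (RPL13, RPL32). qPCR wells are measured in
triplicate. The per-animal measurements behind this design are not
publicly available, so the package generates them synthetically; all
quantitative validation is therefore *parameter- and ordering-recovery*,
not reproduction of any particular empirical table.

## ARE calling

* `scan_pentamers` reports every AUUUA occurrence, overlaps included. A
  pentamer has *U-rich context* when the 20-nt window centred on it is at
  least 60% U; positions beyond the sequence ends count as non-U, which
  makes context calls stable under embedding and the score additive across
  motif-free spacers.
* Class II: at least two chained `UUAUUUA(U/A)(U/A)` cores (overlap or gap
  ≤ 2 nt), each in U-rich context. Class I: at least two context-positive
  pentamers within a 50-nt window. Class III: no pentamer but some 30-nt
  window is ≥ 70% AU and ≥ 40% U. Precedence II > I > III > none. The
  literature definitions are qualitative; the numeric thresholds (60%/20 nt
  context, 50-nt cluster window, 70%/40%/30-nt Class III) are fixed
  module-level constants chosen to separate the canonical motif classes
  cleanly, and are deliberately conservative.
* The numeric ARE score is a local, fully documented surrogate for
  web-service scores (which are neither archival nor published as an
  algorithm): 1.0 per pentamer, +0.5 per context-positive pentamer, +1.0
  per consecutive pentamer pair ≤ 10 nt apart. It is *not* numerically
  comparable to any external service; only the binary call with the strict
  > 3 threshold is consumed downstream. The ARE+ call requires both the
  curated-database membership flag (an input) and score > 3 when a
  sequence is available.
* Coordinates are 0-based half-open; DNA input is transliterated T→U.

## Quantification

* Standard curves: OLS of mean Ct on log10(relative concentration) over a
  five-fold dilution series (≥ 3 levels); efficiency `E = 10^(-1/slope) - 1`;
  R² is the squared Pearson correlation, with a > 0.990 quality gate
  (advisory, logged).
* Sample QC: OD260/OD280 in [1.8, 2.2] (inclusive) and RIN strictly > 7.0.
* Relative expression: replicate Cts are averaged (a replicate range
  > 0.5 Ct logs a warning but does not reject); ΔCt subtracts the
  arithmetic mean of the two reference Cts (equivalently the geometric
  mean of reference expression — the combination rule is not specified in
  the source protocol and this is the conventional dual-reference choice);
  ΔΔCt subtracts the per-gene control-group mean ΔCt (exposed as a choice;
  a single-calibrator alternative would shift all values by a gene-wise
  constant); expression is `(1 + E_target)^-ΔΔCt` with only the target
  gene's efficiency, exactly as the model is printed — no Pfaffl-style
  reference-efficiency ratio.
* Consequences used as test invariants: the control-group geometric mean
  of expression is exactly 1 per gene; expression is invariant to adding a
  constant to all of an animal's Cts; expression is strictly decreasing in
  ΔΔCt.

## Homogeneity metrics

* Per (gene, group): mean, MD (mean absolute deviation), STD (sample SD,
  n−1 denominator — the convention of the usual statistical packages),
  d% = MD/mean × 100, CV = STD/mean × 100.
* CVs: at each contusion time point, genes ranked by ascending CV; with N
  genes, rank positions 1..⌈N/4⌉ score 4 points, then to ⌈N/2⌉ 3, to
  ⌈3N/4⌉ 2, rest 1. Ties break lexicographically by gene symbol so results
  are platform-independent. At N = 28 every time point awards exactly
  70 points (7 genes per quartile). CVs sums over the 12 contusion groups
  only; whether the control group should contribute is ambiguous, so a
  flag (`include_control_in_scores`) exposes both variants, defaulting to
  contusion-only (CV'CV uses the same convention).
* CV'CV: sample SD of a gene's CV series across time points divided by its
  mean, reported as a ratio.
* Subgroup aggregation: each metric is averaged per gene across groups,
  then unweighted across the subgroup's member genes. d% and CV are
  reported as ratios by default (`units="ratio"`), matching the dialect in
  which subgroup summaries of this kind are usually printed; a flag
  switches to percent.

## Wound-age model

* Fisher discriminant = pooled-covariance linear discriminant with all
  variables entered together, equal priors by default (balanced design;
  proportional priors available). No variable selection, no merging of
  time points.
* Wilks' λ = det(W)/det(T); significance by Bartlett's approximation
  `χ² = -(n - 1 - (p + k)/2) ln λ` on `p(k-1)` degrees of freedom.
* Cross-validation is leave-one-out (the "cross-validated" accuracy of
  standard discriminant software), refitting means and pooled covariance
  per fold and accumulating a confusion matrix of held-out predictions.
* Degenerate inputs: the fit requires `n - k > p` and nonsingular scatter;
  collinear gene sets raise an error suggesting the `ridge_epsilon`
  diagonal stabiliser (default off, applied to the pooled covariance used
  for classification only).

## Synthetic generator

* Expression noise is lognormal: `R = exp(profile_g(t) + ε)`,
  `ε ~ N(0, σ_g²)`, so CV on the natural scale is `sqrt(exp(σ²) - 1) ≈ σ`.
  This is equivalent to Gaussian noise on ΔCt and keeps all expression
  positive, so d% and CV are always defined.
* Cycle thresholds invert the quantification model exactly:
  `Ct = Ct0_g - ln R / ln(1 + E_g)` with a per-gene baseline Ct0 in
  [18, 30], gene efficiencies uniform in [0.85, 1.05], triplicate
  technical noise SD 0.05 Ct, and reference-gene σ fixed at 0.02. A
  zero-noise configuration therefore round-trips the planted profiles to
  floating-point accuracy.
* Time profiles are smooth sums of 1-2 low-frequency sine components,
  zero at the control point and scaled to a peak |log2FC| of
  `profile_amplitude` (default 2.0, consistent with candidates that passed
  a |log2FC| > 1 differential-expression screen; settable per subgroup).
  They are synthetic curves, not fits to any published trajectory.
* Default per-subgroup σ: ARE-CC 0.10, ARE-MF 0.15, ARE-BP 0.20, ARE+CC
  0.25, ARE+BP 0.30, ARE+MF 0.35. No per-animal variance magnitudes are
  published for this design, so these are illustrative values spanning the
  10-35% CV range typical of tissue qPCR, graded in the homogeneity order
  the framework is meant to detect, with 0.05 gaps large enough for the
  ordering to be recoverable at n = 6.
* ARE+ UTRs alternate planted Class I and Class II cassettes (both scoring
  4.0 > 3); ARE- and reference UTRs are rejection-sampled to contain no
  AUUUA at all (bounded at 1000 attempts). Class III is never planted: it
  has no constructive definition, and random pentamer-free background
  occasionally satisfies it, which is biologically realistic (diffusely
  AU-rich UTRs exist without functioning as AREs) and does not affect the
  binary call, which keys on database membership plus the pentamer score.
* All randomness flows from one integer seed through independent
  per-stage streams; identical (config, seed) gives byte-identical output
  files.

## What the validation shows — and does not

Passing tests establish that the formulas are implemented exactly (oracle
agreement to 1e-12), that the quantification inverts the generative model,
and that the pipeline reliably recovers homogeneity and accuracy orderings
*planted in the generator* (≥ 95 of 100 seeds). They do not establish that
real contused-muscle mRNAs follow lognormal between-animal variation, that
the planted σ magnitudes match biology, or that any particular published
accuracy would be reproduced: those claims would require the original
per-animal data. The generator also omits features of real qPCR data —
plate effects, occasional failed wells, non-detects at high Ct,
between-run calibration drift — so robustness to those is out of scope.

## Problem sizes

The default validation workload is sized for a laptop-class single CPU:
100-seed ordering studies on the full 78-animal design, 500 noisy
standard-curve fits, 100 label permutations for the classifier null, and
1000-input oracle comparisons; the complete test suite runs in about a
minute.
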