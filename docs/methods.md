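# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic data emulate, and
the limitations a user should know before trusting a result.

## Pipeline model

The data model is a replicate-level intensity matrix: rows are
(sample, replicate) MALDI-TOF readings, columns are mass peaks labeled by
integer-rounded m/z, and the value 0 is a *missing-reading sentinel* that
deliberately conflates "peptide absent" with "reading failed" — handling
that ambiguity is part of the method under test, so no imputation is ever
performed. The stages, in order:

1. **Spectrum preprocessing** (optional, when starting from raw spectra).
   Linear-interpolation resampling onto a uniform m/z grid; global
   alignment by the integer-bin lag maximizing cross-correlation with a
   reference spectrum; peak picking on the mean aligned spectrum as local
   maxima exceeding `snr_threshold` × a MAD-scaled noise estimate above a
   rolling-median baseline, with greedy `min_separation` exclusion;
   quantification as the windowed apex height above baseline, with
   negative or sub-noise-floor values stored as 0.
2. **Replicate summarization.** Per (sample, feature), the unweighted mean
   of nonzero replicate readings (0 only if all readings were 0); then
   removal of every feature with a zero in at least one sample, because a
   margin classifier would otherwise learn the missingness pattern. The
   removal log reports per-class zero counts with a two-sided Fisher
   exact p-value — a diagnostic that dropout is class-blind, never a
   filter.
3. **Control-decile normalization** (per source, before averaging). Per
   (source, feature), thresholds X₁…X₉ are the 0.1…0.9 quantiles (linear
   interpolation of order statistics, h = (n−1)p + 1 — the R type-7
   default) of that source's control-class *nonzero* readings; every
   nonzero reading becomes bin(x) = 1 + #{i : Xᵢ < x}, ties to the lower
   bin, zeros stay 0. Properties relied on downstream: monotonicity,
   scale invariance within a (source, feature) — which is exactly how a
   multiplicative source bias is removed — and trend preservation: a
   feature with opposite class trends in two sources keeps them. Features
   with fewer than two nonzero control readings cannot define deciles and
   pass through unnormalized, flagged with a warning.
4. **Feature selection.** Per-feature two-sided Mann–Whitney U p-values
   (exact when both groups ≤ 8 and tie-free, tie-corrected normal
   approximation with continuity correction otherwise; a constant feature
   gets p = 1) filtered at a p cutoff, optionally combined with a
   max-intensity cutoff (a feature survives if at least one sample's
   averaged reading exceeds the cutoff — the filter removes features,
   never samples). Both cutoffs are optimized by exhaustive grid search
   scored by stratified ten-fold CV accuracy of the downstream
   classifier; among top-scoring combinations the fewest-features one
   wins, remaining ties to the smaller p cutoff then the larger intensity
   cutoff. No multiple-testing correction, by design: the permutation
   control is the guard.
5. **Classification and evaluation.** Maximum-margin linear classifier
   (libsvm linear kernel, C = 1 by default), classes encoded +1 control /
   −1 cancer so a feature's influence wⱼ·Mⱼ (Mⱼ = the feature's maximum
   observed value) reads minus = pushes toward cancer, plus = toward
   control. Reports carry confusion counts (cancer positive), accuracy,
   and MCC, with the zero-denominator convention MCC = 0. Cross-source
   experiments pool the second source's samples with the third source's
   controls (or the held-out cancers with the third source's controls for
   mixed plans) into one validation confusion table.
6. **Clinical rules.** From immunoassay records, the 4-feature panel
   (apoC-I/apoB-100, apoC-III/apoB-100, CRP, CA19-9); apoB-100 is a valid
   denominator because its serum level shows no class trend. The rule
   inducer is a CART-style binary tree (Gini impurity, midpoint
   candidate thresholds, equal-gain ties resolved to the lowest feature
   index then lowest threshold, so training is deterministic and
   record-order invariant). The tree inducer is intentionally generic:
   the scientific content is the feature set and the cross-source
   train/validate protocol, not the particular inducer.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| grid step | 0.5 | Da | linear-TOF peptidome practice; peak widths of a few Da are well sampled |
| alignment max shift | 2 | Da | instrument drift scale; refused above 10% of the grid span |
| baseline window | 50 | Da | wide enough to pass under peptide peaks, narrow enough to track the matrix hump |
| SNR threshold | 5 | — | standard conservative pick threshold against MAD noise |
| min peak separation | 4 | Da | below this, linear-TOF peaks are unresolved anyway |
| noise floor | 3 × noise | intensity | readings below it are indistinguishable from baseline; stored as 0 |
| p-value grid | 15 points, 10⁻³…10⁻¹ log-spaced | — | spans the cutoffs useful in practice |
| intensity grid | 0, 50, …, 500 | intensity | disabled (NA) when normalization is on: bins have no raw scale |
| CV folds | 10 | — | stratified, fixed seed |
| margin constant C | 1 | — | conventional default; exposed in config |
| tree max depth / min leaf | 4 / 5 | — | keeps the rule set readable as a clinical score |

The margin solver is iteration-capped at 200 000 — unreachable for any
well-posed fit, but it bounds runtime on degenerate inputs (signal-free,
unscaled intensity matrices) where the SMO solver otherwise grinds for
minutes toward an equally useless optimum.

## The synthetic-data generator

The generator emulates the two-biorepository study design with known
ground truth. Per feature: a base log-intensity drawn log-uniformly over
50–5000; a per-(feature, source) multiplicative bias exp N(0, σ_src²),
σ_src = 1.0 (up to several-fold between sources — the magnitude needed to
reproduce a near-zero cross-source MCC without normalization); a feature
class — concordant (5%, same-sign class shift in both case/control
sources), discordant (2%, opposite signs), or null (93%) — with log-scale
effect size 1.2 for discriminative features. Per sample: biological
variation N(0, 0.6²) on the log scale (without it every sample would be a
replicate of the class mean and every rank test degenerate). Per reading:
multiplicative log-normal noise at CV 0.35, then dropout to 0 with
probability 1/(1 + exp(s·(log I − log m))), steepness s = 2.5, midpoint
m = 25, so missing readings concentrate at low intensity. Sample sizes
default to the study design: source A 21 control / 22 cancer, source B
20 / 40, source C 12 controls only, two replicates per sample (three
available by option; the real replicate count was "two to three").
The replicate count, like every number above, is a config field.

Spectra can be rendered from any replicate matrix as sums of Gaussian
peaks (σ = 2 Da) on an exponentially decaying baseline with additive
noise, so the preprocessing chain is testable end to end; feature m/z
positions are drawn with a minimum 8 Da gap so planted peaks are
resolvable at the default separation.

The clinical-cohort generator draws the five markers log-normally with
class-dependent locations (apoC-I 80 vs 50 µg/ml, apoC-III 12 vs 8
mg/dl, CRP 3 vs 15 µg/ml, CA19-9 10 vs 40 U/ml, apoB-100 100 mg/dl in
both classes), magnitudes in the range of clinical serum chemistry, with
cohort sizes mirroring the study's clinical arm (A 33/70, B 19/20).

**What the synthetic design does not emulate:** isotope envelopes,
adducts, detector saturation, correlated features (peptides from one
parent protein), stage structure within the cancer class, and any
non-multiplicative source effect. Passing tests therefore establish that
the pipeline recovers the *kind* of structure the design assumes — not
that it would reach any particular accuracy on real sera, whose headline
numbers depend on the undeposited original cohorts.

## Statistical properties worth knowing

* **Source confounding is real and intended.** With the default
  unbalanced design (source B is 2:1 cancer), per-feature source bias
  makes the raw mixed-set rank test wildly anti-conservative (~30% of
  null features at p < 0.05) — this is the cross-source failure mode the
  pipeline exists to treat, and the null-control tests therefore use an
  exchangeable null (no source bias) when checking p-value uniformity.
* **Mild in-sample anti-conservatism after normalization.** The control
  class defines the decile thresholds, so its binned values are
  underdispersed relative to the out-of-sample cancer class; on null
  data ~8% of features reach p < 0.05 after normalization. Users doing
  inference (rather than selection for a cross-validated classifier)
  should know the selection p-values are not calibrated test p-values.
* **Selection happens outside the CV loop**, as in the original
  protocol; the cross-validated accuracy of the winning cutoff pair is
  therefore optimistically biased, which is why the permutation control
  (full re-selection per label shuffle) is part of the evaluation
  surface.
* **Panel comparisons** (4-feature clinical tree vs its 2-feature
  halves) are made on training-source accuracy; at the validation
  cohort's size (~40 sera) the cross-source comparison is dominated by
  sampling noise.

## Numerical conventions

Quantiles: linear interpolation of order statistics. Decile bin ties go
to the lower bin. MCC with a zero marginal is 0. Zero-feature selections
score CV accuracy 0 (no majority-class fallback). Constant features get
rank-test p = 1; a constant vector makes Kendall's τ an error, and a
constant pooled sample makes the one-sided rank test return p = 0.5 with
a warning. Matrix writers emit TSV with 6-significant-digit floats, UTF-8
and LF endings; duplicate integer m/z labels get ".1", ".2" suffixes.
Every CLI run writes a provenance block (parameter hash, seed, input
SHA-256s) beside its output.

## Known limitations

The preprocessing dialect (resampling, alignment, baseline, SNR
thresholds) follows standard linear-TOF practice rather than any
particular instrument vendor's; all constants are config keys so other
dialects can be expressed. The third, control-only source is normalized
by its own control map — the only well-defined choice for a source with
no cancer class. Holdout draws, CV folds and every stochastic step are
seeded; results are bit-reproducible given (data, plan, seed).
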