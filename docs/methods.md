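# Methods

## The diagnostic problem and the pipeline's shape

The package models a three-cohort diagnostic study: healthy controls
(HC), post-surgical patients with sterile systemic inflammation (PS) and
confirmed sepsis patients, profiled on a fixed panel of diagnostic
expression markers plus reference (normalization) genes measured by
real-time PCR. Four pairwise questions are asked, each as a binary
classification: inflamed-vs-healthy (MI = PS ∪ SEPSIS vs HC), each
inflammation type vs HC, and the clinically decisive sepsis-vs-PS. The
pipeline runs in four stages — quantification, screening,
classification, validation — each usable on its own.

## Synthetic study generator

No real measurements ship with the package; the generator produces data
with the statistical structure the downstream stages assume.

* **Cohorts.** Defaults are 20 HC + 38 PS + 27 sepsis = 85 samples,
  ordered HC, PS, SEPSIS with deterministic sample ids.
* **Expression.** Log2 relative fold changes are drawn independently as
  Normal(μ(marker, cohort), σ(marker)). Gaussian noise on the log2
  scale is the conventional model for relative-quantification data and
  makes effect sizes readable in doublings. Defaults place signal on 20
  of the 42 markers — μ = 0 for HC everywhere, 1.5 log2 units for PS and
  1.5 + 0.75 for sepsis on informative markers, σ = 1 — so that (a) the
  sepsis-vs-PS contrast is the hardest one, (b) discrimination survives
  on small random sub-panels (signal is distributed, not concentrated),
  and (c) the resulting AUC summaries land in the high-0.8/low-0.9
  range a real multi-marker sepsis panel reports. These are stand-ins,
  surfaced in `EffectModel`/`RunConfig` rather than hard-coded.
* **Amplification curves.** Each well's noiseless trace is a
  four-parameter logistic b + F_max/(1 + exp(−k(c − c₀))), sampled at
  integer cycles (default 40), with optional additive Gaussian noise
  and F_max = 0 for no-template negative controls. The logistic's
  second derivative peaks at c₀ − ln(2+√3)/k, giving a closed-form
  oracle for take-off estimation; the generator positions c₀ so the
  analytic peak sits at the requested take-off. Default slope k = 0.6
  per cycle: a rise spread over several cycles, and gentle enough that
  the quadratic sub-cycle interpolation of the integer-sampled second
  difference stays within 0.2 cycles of the analytic optimum at every
  phase (steeper curves concentrate the peak between samples and
  inflate the interpolation error).

What the generator does **not** emulate: marker-marker correlation,
batch and plate effects, heteroscedastic or heavy-tailed noise,
amplification inhibition and other real-chemistry pathologies.
Passing tests therefore certify the *procedures* — their calibration,
determinism and oracle agreement — not clinical performance on real
blood samples.

## Quantification

* **Take-off (Cq).** The point of peak cycling acceleration: the
  maximum of the discrete second difference of the (optionally
  moving-average smoothed) trace, refined by a quadratic through the
  peak and its two neighbours (offset clamped to ±half a cycle).
  Detection requires the peak to exceed 5× the median absolute second
  difference of the first 10 cycles — a robust baseline-relative rule
  that keeps noisy no-template wells NOT_DETECTED; wells failing it
  return NOT_DETECTED rather than a number.
* **Pfaffl ratio.** fold = E_t^ΔCt(t) / E_ref^ΔCt(ref) with ΔCt
  oriented (reference − sample) so higher expression ⇒ fold > 1, and
  efficiencies constrained to (1, 2] (default 2.0 for every assay,
  overridable per marker). At E = 2 the ratio is exactly 2^−ΔΔCt.
* **Multiple reference genes** are combined by the geometric mean of
  their per-gene ratios — the accepted multi-reference convention; it
  makes marker fold changes scale-consistent (multiplying every
  normalizer ratio by κ divides every marker fold change by κ).
* **QC.** A plate passes iff all five negative controls are
  NOT_DETECTED and all five positive controls amplify; count mismatches
  and failing wells are reported as reasons, not exceptions.
  Quantification of a failed plate raises `PlateQCError`; a sample
  whose normalizer is undetected raises `SampleUnquantifiableError`.
* **Interpretation note.** The take-off cycle is treated as the
  Ct-equivalent entering the ratio. An alternative reading — taking the
  fluorescence fold change directly at the acceleration peak — exists
  but is not implemented; the Ct-style reading is the one with a
  well-defined efficiency correction.
* **Reference sample.** The calibrator is supplied explicitly as a
  per-marker table of reference take-offs (pooled reference or
  per-plate calibrator both fit this contract).

## Screening

* The inclusion filter keeps a marker iff signal > 100 **and** fold
  change > 2.0, strictly. Fold change is two-sided by default
  (max(r, 1/r)), with a config flag for up-regulation only; the signal
  scale is whatever the caller supplies (linear by convention).
* The moderated t shrinks per-marker pooled variances toward a prior:
  s̃² = (d₀s₀² + d·s²)/(d₀ + d), t̃ = Δmean/(s̃√(1/n₁+1/n₂)), p from a t
  distribution on d₀ + d df. When (d₀, s₀²) are not supplied they are
  estimated by method of moments using the marginal result
  s² ~ s₀²·F(d, d₀): the dispersion ratio Var(s²)/E(s²)² identifies d₀,
  the mean then gives s₀². Under-dispersed variance sets (ratio at or
  below the pure-chi-square level) get d₀ = 10⁶, i.e. effectively a
  common-variance t. With d₀ = 0 the statistic is exactly the ordinary
  pooled-variance two-sample t. This is deliberately a two-group
  implementation, not a general linear-model framework — two-group
  contrasts are the only ones the pipeline uses.
* Holm's step-down adjustment is implemented from its defining formula
  (sorted ascending, p̃_(i) = max_{j≤i} min(1, (m−j+1)p_(j))) and tested
  against statsmodels' implementation.

## Classifier

Binary LogitBoost with depth-1 regression stumps:

* initialize F = 0, p = ½; per iteration set w = p(1−p) (floored at
  2·machine-epsilon), z = (y* − p)/w clamped to ±z_max (default 4), fit
  the exact weighted least-squares stump over all features and all
  thresholds midway between consecutive sorted unique values, update
  F ← F + ½f, p = 1/(1+e^−2F);
* M defaults to 50 with early stop once the training negative
  log-likelihood improves by < 10⁻⁶ (small panels saturate quickly);
* ties in stump loss break toward the smallest threshold, then the
  smallest feature index, making fitting fully deterministic — there is
  no randomness anywhere in the learner;
* the stump search is vectorized: the per-feature sort order is
  computed once per training set and reused across iterations, so one
  fit costs O(M·n·p) after an O(n log n · p) presort. This is what
  keeps 500-partition evaluations in seconds.

Known behaviour worth understanding: on data separable by a single
feature the log-likelihood saturates after very few iterations, the
early stop triggers, and the ensemble is effectively a one-feature
rule with posteriors saturated near 0/1. Held-out performance is then
bounded by one-feature generalization, and AUCs computed from such
binary-valued posteriors are quantized (they reduce to
(sensitivity + specificity)/2). With signal distributed over many
modestly-shifted markers — the regime the generator defaults to — the
ensemble spreads over features and this effect disappears.

Leave-one-out cross-validation refits everything per fold, including
the optional top-k moderated-t marker pre-selection (off by default:
the full supplied panel is used), so a sample's prediction never sees
its own label.

## Evaluation

* **ROC/AUC** by the rank (Mann-Whitney) method, ties counting ½;
  verified exactly against brute-force pair enumeration.
* **Repeated random partitioning**: B = 500 iterations by default; each
  draws a stratified split with a 2/3 training fraction (clamped so
  both halves keep ≥ 2 members of each class — with 20-38-sample
  cohorts unstratified splitting would regularly starve a class), fits
  LogitBoost with a fixed configuration on the training half and
  records the validation AUC; reported as mean ± SD.
* **Permutation null**: each of B iterations couples one fresh uniform
  label permutation with one fresh partition and one fit/score cycle.
  The one-sided empirical p for the observed mean AUC is the add-one
  estimator (1 + #{null ≥ observed})/(B + 1); it can never be 0 and its
  floor at B = 500 is 1/501 ≈ 0.002. The observed statistic is the mean
  of the observed AUC distribution — a deliberate choice, since the
  procedure compares distributions rather than a single split.
* **Seeding**: one root seed; observed and null runs draw from separate
  spawned SeedSequence streams, one child stream per iteration, so each
  run is independently reproducible and the two never share draws.
* **Sub-panel evaluation** reruns the identical pipeline on a marker
  subset (the 7-vs-42 redundancy comparison); **PCA scores** are the
  column-centered SVD projection for cohort visualisation.

## Orchestration

`run_study` executes simulate → (optional curve simulation +
quantification round trip) → screening (MI vs HC) → evaluation of all
four comparisons at the full panel and one seeded random sub-panel,
writing TSV/JSON artifacts plus a run log with the resolved seed; rerun
with the same config is byte-identical. Every stage seed is derived
from the root seed through SeedSequence keys.

## Problem sizes in tests

The statistical acceptance tests run at the study's own scale (85 or
65 samples, 42 markers) with B = 500 for the permutation checks and
B = 200 for the monotonicity and redundancy checks, and 500 simulated
datasets for screening calibration; the whole suite completes in well
under a minute. These sizes give Monte-Carlo standard errors of
roughly 0.003-0.006 on mean AUC, comfortably inside the asserted
tolerances (±0.02 on null centering, 0.1 on redundancy).

## Limitations

* Binary formulation only (applied pairwise); no multiclass boosting,
  shrinkage schedules or alternative base learners.
* The moderated t covers two-group contrasts only.
* Independent-marker Gaussian synthetic data; conclusions about real
  correlated panels require real data.
* No sensitivity/specificity tabulation at fixed thresholds — those
  require a clinically sampled population and belong to late-stage
  validation, not to this harness.
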