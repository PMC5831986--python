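# Methods

## PRT calibration and integer calling

A paralogue ratio test yields, per fluorescence channel (assay × dye), a
test/reference peak-area ratio that is affine in the diploid copy number.
Calibration regresses the reference-panel ratios on their known integer copy
numbers (ratio as the response, matching how such panels are used in
practice) and inverts the fitted line for prediction. The per-channel
dispersion `residual_sd` is the standard deviation (ddof = 1) of the
calibrated reference estimates around their known integers; channels with
fewer than 3 residual degrees of freedom fall back to the dispersion pooled
across channels, since a six-sample panel estimates a single-channel sd
poorly. A fitted slope ≤ 0 marks the channel failed (ratios must increase
with copy number); a panel in which every channel fails is a fatal error.

Dye channels within one assay measure the same PCR reaction, so they are
averaged into one per-assay estimate with sd √(Σσᵢ²)/n before pooling; a
`pool="channel"` mode pools raw channels instead for users who prefer it.
The integer call maximises the joint Gaussian log-likelihood over the
support 1..12 (the locus's known diploid range, configurable). Choices that
matter:

* **Likelihood form** — independent Gaussian errors per pooled estimate with
  the calibration-residual sd. This is the standard working model for PRT
  data and the only dispersion information the calibration provides.
* **Confidence** — the normalised likelihood weight L(k*)/Σₖ L(k), computed
  with max-subtraction; it behaves like a posterior probability under a
  uniform prior on the support. Calls below 0.60 carry a `LOW_CONFIDENCE`
  flag but are still emitted.
* **Ties** — broken deterministically to the smaller integer.
* **sd floor** — 1e-3 copies, so a noise-free panel cannot produce a
  degenerate (delta) likelihood.
* **Minimum evidence** — ≥ 2 usable assay estimates; below that the sample
  is a typing failure (`TOO_FEW_CHANNELS`), the mechanism behind the few
  per cent of untypable samples in real cohorts.
* **Support edges** — estimates outside [support_min − 1, support_max + 1]
  are flagged `OUT_OF_SUPPORT` but not clamped; clamping would silently hide
  calibration failures.

## Assay processing

ELISA readings below the 16 pg/ml limit of detection — reported either as a
number under the LOD or as an `ND` token — are substituted by LOD/√2
(≈ 11.31 pg/ml), the conventional single-value imputation for left-censored
biomarkers, and flagged; the flag propagates to derived variables. The
order is fixed: censor first, then normalise to total protein (pg/ml ÷
µg/ml → pg/µg).

Bactericidal activity is %kill = 100·(1 − cfu_test/cfu_control) from
triplicate means, buffer survival defining 100%. Replicate sets need ≥ 2
usable readings; a coefficient of variation above 0.30 raises a QC flag.
Negative %kill (net growth over control) is kept by default
(`allow_negative`) because downstream statistics are rank-based and clipping
only discards information; `clip_to_zero` is available and flags
`GROWTH_OBSERVED`. %kill is normalised by the total protein *concentration*
(µg/ml). With a fixed assay volume the per-aliquot protein mass differs from
the concentration only by a constant factor that cancels from every rank
statistic; the concentration basis also keeps %kill magnitudes on the
percent scale, where cohort medians near 0.05 %kill/µg coexist with
replicate noise of a percentage point or two — on a per-aliquot-mass basis
the same medians would force %kill values an order of magnitude below that
noise. The OD600 → cfu conversion is upstream of this package: it ingests
cfu/ml directly because no conversion curve is portable across instruments.

## Association layer

Spearman's ρ is the Pearson correlation of mid-ranks (average ranks on
ties), on pairwise-complete observations, with n ≥ 3 required for a result.
The two-sided p-value is exact by full permutation enumeration for n ≤ 9
without ties, and otherwise uses t = ρ√((n−2)/(1−ρ²)) on n − 2 degrees of
freedom; every result records the method actually used. No multiplicity
correction is applied by default — the pairwise p-values are reported raw,
as is conventional for small descriptive matrices — and the correlation
copy-number variable is the continuous weighted mean (the integer call is
available as an alternative).

Exclusions are two-tier: women starting progesterone before sampling are
removed from every analysis set; post-sampling interventions (cerclage,
progesterone) and pregnancies ending in miscarriage or termination are
additionally removed from the outcome-stratified set only, since these
either alter the outcome or remove it. Each exclusion is written to an
audit table (sample, rule, set). Strata with n < 3 are reported with an
`UNDERPOWERED` note instead of a ρ; computable strata under n = 30 carry the
same note alongside their result, because a preterm stratum of ~14 cannot
distinguish moderate correlations from zero.

The two-group comparison is Mann–Whitney U (no distributional assumption is
defensible for these skewed variables). The p-value is exact by full
enumeration of group assignments when C(n₁+n₂, n₁) ≤ 2·10⁵ — this handles
ties and returns p = 1 for identical groups; otherwise exact via the
tie-free U distribution when min(n) ≤ 8; otherwise a tie-corrected normal
approximation with continuity correction. Full enumeration at min(n) ≤ 8
against a large complementary group is combinatorially impossible, which is
why the cap exists.

## Synthetic cohort generator

The generator emulates an antenatal cohort of n = 203 (default):

* **Copy number** — discrete prior on 1..8, mode 4
  (probabilities 0.005/0.06/0.25/0.38/0.21/0.08/0.012/0.003). Only the
  range and mode are anchored to real cohorts; the shape is free
  calibration.
* **Gestational age** — scaled Beta(2, 3.5) on [61, 192] days. A uniform on
  that range would put the median at 127 days, inconsistent with the target
  median of 107 (15 weeks 2 days); the Beta shape matches the median within
  the range, and monotone reshaping cannot affect rank statistics.
* **HBD2** — log h = log 1.2 + β_cn(c − 4) + β_ga(g − 107)/7 + ε with
  β_cn = 0.29, β_ga = −0.11, ε ~ N(0, 1.34²). The log-linear Gaussian form
  is the simplest model giving tunable Spearman structure on a positive
  variable.
* **Activity** — log k = (log 0.049 − 0.10) + 0.65·(log h − log 1.2)
  + 0.11·(c − 4) + η, η ~ N(0, 1.30²). The small direct copy-number term
  lets ρ(cn, kill) reach ≈ 0.17 where mediation through HBD2 alone yields
  ≈ 0.10. The −0.10 intercept offset compensates the upward shift of the
  emergent cohort median caused by additive replicate noise on the
  right-skewed %kill scale.
* **Measurement layers** — raw ELISA = h × protein with protein log-normal
  (median 80 µg/ml, log-sd 0.5), putting ~12% of raw values below the
  16 pg/ml LOD; PRT ratios 0.5·c·(1 + N(0, 0.05)); triplicate cfu with 2%
  CV; typing failure (rate 0.044) implemented by zeroing all but one
  assay's channels so the caller's own minimum-evidence rule produces the
  failure; a 6-sample reference panel at copy numbers 2–7 measured under
  the same noise model.
* **Outcome and flags** — Bernoulli: preterm 14/167, cerclage 20/203,
  post-sampling progesterone 2/203, miscarriage and termination 1/203 each,
  pre-sampling progesterone 6/209. Outcome is independent of the biology by
  default (couplings can be added for power studies).

Every component draws from its own substream spawned from the single seed
(fixed spawn order), so changing one rate leaves all other components'
draws byte-identical — a property the tests assert.

The correlation-bearing coefficients were first derived from the target
Pearson/Spearman relations and the configured variances, then refined by
replicate simulation of the *full pipeline* (generation, calibration,
calling, censoring, normalisation, correlation) until the 200-replicate mean
of each pairwise Spearman ρ sat within ±0.05 of its configured target
(`target_rho`: +0.21, −0.25, +0.49, +0.17). The generator's
`calibration_report` re-runs that check on demand.

### What the generator does and does not emulate

It reproduces the rank-correlation structure, censoring fraction, typing
failure rate, marginal medians and skew, outcome and exclusion rates of a
realistic cohort. It does **not** model: inflammation-driven HBD2
induction (the biological confounder most likely to distort the
copy-number–protein relation in vivo), batch or plate effects, within-woman
longitudinal structure, assay drift, or any outcome–biology coupling.
Passing tests therefore demonstrate that the pipeline recovers structure
faithfully when its statistical assumptions hold — not that those
assumptions hold in any particular clinical dataset.

## Problem sizes and numerical choices

Replicate studies use 200 cohorts of n = 203 (the acceptance script) —
enough for the Monte-Carlo standard error of a mean ρ to be ≈ 0.005, an
order of magnitude below the ±0.05 calibration band. The noisy-recovery
check uses 5 cohorts of n = 200 at 5% channel CV, where the pooled estimate
sd (~0.13 copies) makes ≥ 95% correct integer calls for true copy number
≤ 6 comfortably identifiable. Exact enumeration limits (Spearman n ≤ 9,
Mann–Whitney C ≤ 2·10⁵) keep exact inference where it is feasible and
switch to standard approximations where it is not. Floating-point guards:
max-subtraction in the likelihood normalisation, a 1e-3-copy sd floor, a
1e-12 tolerance when counting permutation ties.

## Known limitations

* The Gaussian error model for pooled PRT estimates ignores occasional
  heavy-tailed outliers real capillary data produce; a robust variant would
  need a contamination model the calibration panel cannot estimate.
* LOD/√2 single-value substitution biases variance estimates of censored
  variables; it is retained because the downstream statistics are rank-based
  and the convention is standard for this assay class.
* The exact Mann–Whitney path is unavailable for a small group against a
  very large one (enumeration cap); the tie-corrected normal approximation
  used there is adequate at the cohort sizes involved.
* Spearman p-values for heavily tied small samples use the t approximation;
  an exact tie-aware enumeration would require multiset-permutation logic
  whose benefit is negligible at the n where it is feasible.
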