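# Methods

## Scope

The package estimates how CSVD burden grade moderates the association
between plasma p-tau181 and downstream markers of axonal injury (NfL),
white-matter microstructure (tract-wise DTI metrics) and cognition, and
decomposes the p-tau → cognition pathway into indirect effects through
NfL and the left cingulum.  All imaging inputs are tract- and
region-level scalars; image acquisition, segmentation and visual CSVD
feature rating are upstream of this package and out of scope.

## Cohort construction

* **CSVD burden**: total score = sum of four binary MRI features
  (lacunes, microbleeds, severe basal-ganglia enlarged perivascular
  spaces, severe WMH); grades: none (0), mild (1), moderate-to-severe
  (≥ 2).  The mapping is total and validated against exhaustive
  enumeration of all 16 feature patterns.
* **Exclusions**: NfL strictly above 179 pg/ml (a screen against severe
  unrelated CNS disease), and missing values in required biomarker or
  cognition columns.  Rules are applied in one conjunctive pass; each
  removed row is attributed to the first rule it violates, so the
  per-rule counts sum exactly to the total removed.
* **Aβ positivity**: a two-component univariate Gaussian mixture is
  fitted to Aβ42 by EM (median-split initialization plus 9 random
  restarts, tolerance 1e-8 on the log-likelihood, variance floor
  1e-4 × data variance; the log-likelihood is asserted non-decreasing at
  every iteration).  The cut-off is the equal-posterior point between
  the component means; positivity defaults to *at-or-above* the
  cut-off, configurable, since plasma Aβ42 conventions differ between
  assays.  On synthetic cohorts Aβ42 is generated unimodal, so the
  cut-off there only exercises the machinery; it is meaningful on real,
  bimodal data.
* **WMHV tertiles**: rank-based thirds with remainders allocated to the
  lowest tertile(s) and ties broken by stable input order.
* **Standardization**: z-scores with the n−1 denominator.  Default
  scope is *full sample*, so per-stratum coefficients share a scale and
  between-stratum Δβ values are meaningful; within-stratum scope is
  available and recorded in the frame's provenance attribute.

## Inference

* **Adjusted linear models**: OLS with the focal predictor and outcome
  z-scored, covariates (age, sex, education, hypertension, diabetes,
  intracranial volume, Aβ positivity as 0/1) on their native scale.
  Rank-deficient designs raise an error naming the collinear columns.
  Complete-case analysis per model.
* **Interaction coding**: the burden grade enters ordinally (0/1/2) by
  default, giving a single one-degree-of-freedom interaction estimate;
  dummy coding is available by flag.  With two groups and no
  covariates, the dummy-coded product coefficient equals the difference
  of within-group slopes exactly (tested to 1e-10).
* **BCa bootstrap**: B = 5000 resamples by default, drawn within
  strata when a grouping is given (between-grade contrasts resample
  each grade independently; the groups are disjoint participants).
  Bias correction z₀ = Φ⁻¹(#{θ* < θ̂}/B); acceleration from a
  delete-one jackknife over all rows,
  a = Σd³ᵢ / (6·(Σd²ᵢ)^{3/2}) with dᵢ = θ̄₍·₎ − θ₍ᵢ₎.  Replicates where
  the statistic fails or is non-finite are redrawn (cap 2B, count
  reported).  Degenerate cases are explicit: identical replicates raise
  an error; a zero jackknife spread falls back to percentile bounds
  with a recorded warning; extreme bias proportions (0 or 1) are
  clipped to 1/(B+1).  Standardization is treated as a fixed
  pre-processing step: resamples reuse the full-sample z-scores rather
  than re-standardizing, which keeps the contrast point estimate
  identical to the difference of stratified estimates.
* **Significance**: an effect is called significant when its BCa
  interval excludes zero at the configured level (0.90 primary, 0.95
  as a stricter variant); p-values are additionally reported for the
  interaction model.
* **FDR**: Benjamini–Hochberg step-up within each family × effect set
  (48 tracts per metric; 124 regions).  Pooling tract metrics into one
  144-test family is deliberately *not* the default.
* **Path model**: three OLS equations fitted sequentially on the
  standardized roles; for a recursive system with uncorrelated Gaussian
  errors this coincides with full-information maximum likelihood, which
  the test suite verifies against a direct numerical maximization of
  the joint log-likelihood (1e-6 on all six coefficients).  Path
  covariates default to age, sex and education (`methods_text` preset);
  a fuller vascular set is available as the `figure_legend` preset —
  which set produced any given published estimate is generally not
  determinable from figure annotations, so both are exposed.  MD enters
  with its natural sign (higher = worse integrity), so β₃ < 0 against
  cognition is the expected direction.

## Synthetic cohort generator

The generator emulates the statistical structure the inference assumes,
with every parameter known:

* **Composition** is deterministic: 144/103/128 participants per grade
  and a 70/41/17 split of grade-II scores 2/3/4, exact for every seed.
  Which feature subset produces a given score is uniform over subsets
  of that size (feature co-occurrence is not otherwise constrained).
* **Covariates and biomarkers** follow per-grade moments typical of an
  elderly memory-clinic cohort (age ≈ 66→73 years across grades,
  hypertension 28→54%, WMHV 6→19 ml).  p-tau181, Aβ42, Aβ40, GFAP and
  WMHV are log-normal (their SDs are comparable to their means,
  implying right skew); effects are specified on the standardized
  scale and applied to full-sample z-scores, matching the analysis
  scope.
* **NfL** is linear-Gaussian on the measured scale:
  NfL = μ_g + σ·(β₁⁽ᵍ⁾·z(p-tau) + 0.15·z(age) + ε) with
  β₁ = (0.06, 0.08, 0.30) and a *common* within-grade σ = 15.74 pg/ml
  (per-grade SDs would rescale the standardized slopes away from their
  configured values).  The Gaussian tail admits occasional
  non-physical negative values; they are retained because truncation
  would bias the slopes the generator promises.
* **Tract metrics** map unit-variance latents onto physical units
  (FA 0.45 ± 0.035, MD 0.80 ± 0.045 ×10⁻³ mm²/s, MO 0.35 ± 0.15) with
  small grade and age main effects — kept small on purpose, since large
  between-grade mean shifts would inflate the full-sample SD and put
  the planted standardized effects off contract.  FA/MD/MO bounds are
  enforced by truncation with a logged count (< 1% under defaults,
  in practice zero).
* **Planted effects**: interactions only in the two left cingulum MD
  members (0.16 cingulate part, 0.15 hippocampal part); main effects in
  fornix-cres/stria-terminalis and posterior thalamic radiation; weak
  main effects on medial-temporal volumes that do not survive FDR at
  n = 375.  Tract effects are *marginal* targets; the mediator's
  conditional path coefficient is derived as
  β₄⁽ᵍ⁾ = marginal⁽ᵍ⁾ − β₂⁽ᵍ⁾β₁⁽ᵍ⁾, so the mass-univariate marginal
  interaction (≈ 0.16) and the path-model contrast
  (Δβ₄(II−0) ≈ 0.277) arise from one coherent data-generating process.
* **Cognition** is generated from the path equations with per-grade
  (β₂, β₃, β₅, c′) chosen so that the true total-indirect-effect
  difference ΔIE(II−0) ≈ −0.10; domain scores are unit-variance
  z-scores, MMSE/MoCA are rescaled, rounded and clipped integer
  transforms of the same latent (the rounding attenuation is
  negligible at the configured scales).
* **Reproducibility**: one global seed feeds per-column substreams
  keyed by CRC32 of the column name, so adding or re-parameterizing a
  column never perturbs others; two runs with the same seed are
  byte-identical.

What the generator does **not** emulate: bimodal Aβ42, biomarker
cross-correlations beyond the modeled paths, measurement error in the
CSVD feature ratings, spatial correlation among tracts/regions, floor
and ceiling effects in cognitive tests beyond simple clipping, and
missing data (exclusion logic is exercised with crafted inputs in the
tests).  Passing recovery tests therefore demonstrates estimator
correctness under the assumed structure, not robustness to violations
of it.

## Simulation design in the tests

Parameter-recovery checks use 200 independent default cohorts
(point estimates only; the bootstrap is exercised separately at
B = 300–1000).  Calibration uses 1000 repetitions at B = 2000 for BCa
coverage of a Gaussian mean (accepted band 0.87–0.93 at the 90% level),
150 null repetitions for the between-grade contrast false-positive
rate (compared against 10% with a two-binomial-SD Monte-Carlo margin),
and 500 repetitions of a 48-feature global null for the per-family FDR
hit rate (≤ 7%).  The acceptance script reuses the same designs at
100–500 repetitions.

## Known limitations

* Negative synthetic NfL values (see above) — harmless for the linear
  analyses, but a visible non-physicality of the emulation.
* BCa intervals at n ≈ 100 per stratum undercover slightly
  (≈ 88–89% observed at the nominal 90%), a well-known small-sample
  property of the method rather than an implementation defect.
* The single-realization pipeline output is noisy by design at
  n = 375; only repetition averages are compared against the
  generator's truth.
* Grade-II's single ordinal interaction coefficient summarizes a
  slope profile (0.06/0.08/0.30) that is not actually linear in grade;
  the implied ordinal estimate (≈ 0.118 under the design weights) is
  what recovery is checked against.
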