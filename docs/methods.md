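# Methods

## The problem

Bioelectrical impedance analysis (BIA) yields three body-composition
outcomes per participant: relative fat mass (RFM, % of body weight),
visceral adipose tissue (VAT, kg) and the skeletal muscle mass index
(SMI = SMM / height_m², kg/m²). A 3D surface scanner yields ~30 continuous
shape measures (girths and lengths in cm, segment volumes in litres) that
are strongly mutually correlated. The package answers two questions, always
separately by sex: *which combination of scanner measures predicts each
outcome stably*, and *how much explained variation that combination adds
over single standard measures* (BMI, waist circumference, waist-to-height
ratio; for SMI also forearm and thigh girths), before and after adjusting
for age and lifestyle (education, physical activity, Diet Quality Index).

## Variable selection

Selection is linear-model backward elimination wrapped in a bootstrap:

1. **Backward elimination.** Starting from the model containing all
   candidates, the variable (or whole dummy block, for a categorical) whose
   removal most improves the criterion is dropped until no removal improves
   it. The default criterion is AIC (computed as for a Gaussian likelihood,
   identical to `statsmodels.OLS(...).fit().aic`); p-value-based removal
   (largest partial-F p above `alpha`) is available via `criterion="pvalue"`.
   AIC stepwise retains a pure-noise variable with probability
   P(χ²₁ > 2) ≈ 0.157, so on null data it keeps ≈ 0.16·p variables; the
   p-value criterion at α = 0.05 keeps almost none. Ties are broken by
   variable name, which makes the path deterministic and invariant to
   candidate ordering.
2. **Bootstrap inclusion frequencies.** The elimination is rerun on
   B = 2000 resamples (rows drawn i.i.d. with replacement within the sex
   stratum; desk-scale tests use B = 200). A variable's inclusion frequency
   is the fraction of resamples in which it survives; its fitted
   coefficients from exactly those resamples form its draw distribution.
   Replicates whose full design is singular are redrawn, with a warning
   above a 1% redraw rate. Per-replicate RNG streams come from a
   counter-based `SeedSequence` scheme, so results are reproducible given
   one seed and independent across replicates.
3. **Two-step stable set.** Variables with inclusion frequency **> 0.70**
   are then kept only if the 95% **BCa interval** of their coefficient
   draws has two endpoints of the same nonzero sign. An endpoint exactly at
   zero counts as sign-ambiguous.

### BCa intervals

For draws θ*₁…θ*_B and full-sample estimate θ̂:

* bias correction `z0 = Φ⁻¹(#{θ* < θ̂}/B)`, with the proportion clamped to
  `(count + 0.5)/(B + 1)` (and flagged) when the count is 0 or B;
* acceleration `a = Σ d³ / (6 (Σ d²)^{3/2})` with `d_i = mean(jk) − jk_i`
  over jackknife (leave-one-observation-out) coefficient estimates of the
  model containing the frequency-filtered variables, computed by the exact
  hat-matrix downdate (no refit loop);
* the interval is the pair of empirical quantiles of the draws at
  `Φ(z0 + (z0 + z_{α/2})/(1 − a(z0 + z_{α/2})))` and the analogous upper
  level. With z0 = 0 and a = 0 this is exactly the percentile interval.
  Identical draws yield a degenerate, flagged interval.

Coefficient draws are **conditional on selection** by default; a
zero-imputation variant (padding the unselected replicates with zeros) is
available via `zero_imputation=True`. Conditional draws are the
interpretable choice for a sign filter — they ask "when the variable is in
the model, is its effect direction stable?" — but they are biased away from
zero for rarely-selected variables, which is why the frequency filter comes
first. Monte-Carlo coverage of the interval for a normal mean (n = 50,
B = 2000) measures ≈ 94%, the well-known mild small-sample undercoverage
of BCa.

## Validation and agreement

* **Bootstrap out-of-bag validation**: per iteration the selected model is
  refitted on a resample and scored on the rows not drawn (R² about the
  out-of-bag mean, unclipped and possibly negative; RMSE in outcome units);
  means over 2000 iterations are reported next to the apparent adjusted R²
  of the full-data fit. OOB scoring is pessimistic by roughly 0.03–0.04 in
  R² at n = 200 because each fit sees ~63% of the rows; a
  `method="resample"` variant (score on the full sample) is available.
* **Bland–Altman**: differences d = measured − predicted; limits of
  agreement mean(d) ± 1.96·SD(d) (the literal 1.96, not a t quantile);
  proportional-bias slope = OLS slope of d on the pairwise means.
* **Spearman ρ** is the Pearson correlation of mid-ranks (scipy), with
  constant inputs flagged NaN.

## The model ladder

Per outcome and sex the ladder fits: age alone, lifestyle alone, each
single-measure baseline (+ age, + age + lifestyle), and the stable scan
model (+ age, + age + lifestyle). Lifestyle always counts as **3
variables** (education, activity, diet) irrespective of dummy expansion,
so "BMI + age + lifestyle" has N = 5. The `improvement_summary` is the
best scan-family adjusted R² minus the best standard-measure adjusted R²,
in percentage points. Selection is rerun per outcome and sex; stable sets
are never shared across strata.

## Synthetic cohorts

The generator emulates a scanner + BIA study population with known truth:

* **Correlated measures**: a 3-factor Gaussian model (overall size, central
  adiposity, limb muscularity). Loadings are assigned by measure category
  (central / limb / frame / size) and scaled by `loadings_scale`;
  per-measure uniqueness is 1 − ‖loading‖², so a scale making that negative
  is rejected as non-PSD. Standardised values map affinely to plausible
  units (means/SDs per sex, girths ~20–130 cm, volumes ~1–40 l).
* **Outcomes**: sparse linear functions of 5 true measures on the
  standardised scale, plus a linear age gradient (age uniform on 18–90;
  RFM +0.12 %/y, VAT +0.03 kg/y, SMI −0.015 kg/m²/y) and Gaussian noise.
  Baseline levels at the midpoint age are sex-specific (men RFM 23.3%,
  VAT 2.6 kg, SMI 9.5; women 30.5%, 0.9 kg, 7.0). The residual SD is
  derived analytically from a target population R² (default 0.80 per
  outcome): `noise_sd² = signal_var · (1 − R²)/R²` with
  `signal_var = βᵀΣβ + slope²·var(age)`.
* **Support calibration**: the default true-support coefficients within an
  outcome are of comparable standardised magnitude (one negative member
  each), so every support member carries a detectable share of signal at
  the default cohort sizes — the calibration a support-recovery testbed
  needs. Heavily unbalanced supports make the weakest member's recovery a
  coin flip at n = 200 and test the generator, not the procedure.
* **Lifestyle** answers are drawn independently of the outcomes (category
  probabilities roughly matching a mixed adult population), which lets
  selection tests isolate the scan measures; confounded lifestyle can be
  emulated by editing the per-sex config.
* **Physical clipping**: RFM to [0, 100] and VAT/SMI to ≥ 0. Under the
  defaults this is rare for RFM/SMI but acts as visible left-censoring for
  women's VAT (a Gaussian at mean 0.9 kg has mass below zero; real VAT is
  right-skewed). Recovery and calibration tests therefore use RFM.
* Weight tracks total body volume (≈1 kg/l plus measurement noise), so BMI
  is a genuinely informative, but incomplete, summary of the truth —
  matching the role single measures play in the comparison.

What the generator does **not** emulate: skewed or heteroscedastic outcome
noise, age-dependent covariance structure, missing-data mechanisms beyond
missing-completely-at-random flags, or measurement error correlated across
scanner measures. Passing tests therefore demonstrate the procedure's
behaviour under a well-specified sparse linear truth with realistic
collinearity — not robustness to misspecification.

## Numerical choices

* The stepwise/bootstrap hot loop uses centred Gram matrices with Cholesky
  solves (subset RSS in O(k³) independent of n); a test pins its AIC and
  coefficients to statsmodels. Final reported fits go through
  `statsmodels.OLS`.
* Cholesky failure marks a subset singular; a singular *full* model is
  repaired by dropping columns beyond the numerical rank (pivoted QR),
  logged.
* SD of a single observation is reported as NaN, never 0.
* WHO-style category bands are closed on the left (e.g. waist 94.0 cm for
  men falls in "94.0–101.9"); the WHtR first band "≤0.5" is closed on the
  right, and the women's WHR ladder is resolved contiguously as
  [0.80, 0.85) then ≥0.85.
* Test and acceptance problem sizes (B = 200, n = 200 per stratum, 20 outer
  seeds, 500 coverage repeats) are the package's desk-scale defaults; the
  procedure's study-scale default remains B = 2000.

## Known limitations

* AIC-based elimination admits correlated false positives by construction;
  the two-step filter removes most but not all. Under the default
  calibrated cohort (n = 200, 30 measures, R² ≈ 0.8) the full procedure
  recovers all 5 true predictors almost always, with ≤ 2 false positives in
  roughly 8 of 10 runs.
* Inference after selection is not multiplicity-adjusted; BCa intervals on
  conditional draws describe stability, not post-selection confidence.
* Complete-case analysis throughout, mirroring the intended study design.
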