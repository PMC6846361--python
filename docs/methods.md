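# Methods

## Estimation formulas and scales

Eight serum-creatinine models are registered. Six estimate GFR —
CamGFR, CKD-EPI (2009), MDRD-186, the Mayo quadratic, Wright, Martin — and
two estimate creatinine clearance — Cockcroft-Gault and Jelliffe. Each
formula is implemented as a vectorized kernel that consumes only named
constants from `gfrbench/data/model_constants.yaml`, so coefficient updates
(or a corrected transcription) never require code changes.

Scale handling is explicit. CKD-EPI, MDRD-186, Mayo and Jelliffe natively
report mL/min/1.73 m²; Cockcroft-Gault, Wright, Martin and CamGFR report
absolute mL/min. Because tracer-measured GFR is absolute and the Calvert
dose equation consumes absolute GFR, normalized outputs are de-normalized by
`value · BSA / 1.73` before any comparison or dosing, with BSA from DuBois &
DuBois (`0.007184 · W^0.425 · H^0.725`, W kg, H cm). Whether Jelliffe should
be de-normalized is genuinely debatable (its original derivation assumed a
1.73 m² adult); the default de-normalizes, and flipping its `native_scale`
in a user constants file switches the behaviour without touching code.

Sex enters every kernel as an enumeration, never as a 0/1 integer, because
the source formulas disagree about which sex the indicator encodes. Missing
race information defaults to nonblack; only CKD-EPI and MDRD-186 carry race
terms.

**CamGFR coefficients are synthetic stand-ins.** The published CamGFR model
is a square-root-scale linear predictor in age, BSA, creatinine terms and
sex with absolute-scale output; its exact coefficient table is not bundled
here. The shipped entry preserves that functional form with coefficients
calibrated once by least squares against CKD-EPI-de-normalized estimates
over a realistic adult covariate grid (age 18–91, BSA 1.2–2.6 m²,
creatinine 0.25–4.5 mg/dL log-uniform, 45% female). The result behaves like
a plausible member of the model family (strictly decreasing in creatinine;
positive everywhere — the root term is floored at 0.1 because the linear
predictor can cross zero at the extreme old/small/high-creatinine corner;
~10 mL/min RMSE from its calibration target, i.e. clearly distinct) and
keeps every structural property of the
registry testable. The `source_ref` string labels it loudly; users with the
published table should load it via `load_constants(path)`.

### A numerical note on the Mayo quadratic

The Mayo exponent `1.911 + 5.249/S − 2.114/S²` peaks at
`S = 2·2.114/5.249 ≈ 0.805` mg/dL, so the published formula *rises* on the
≈0.005-wide interval just above its 0.8 clamp before decreasing. This is not
a transcription artifact — the clamp exists precisely because the quadratic
turns over there. Monotonicity audits therefore use grid spacings (0.05
mg/dL) that bracket the window, and the center-bias tests exclude records
whose biased creatinine lands inside it.

## Cohort rules

Inclusion: age ≥ 18 years ("adult" operationalized at 18, the cohort
minimum); creatinine 0.20–4.5 mg/dL with both bounds inclusive (the natural
reading of "between" is ambiguous; inclusive was chosen and is documented
here); |creatinine date − mGFR date| ≤ 30 days, two-sided, in whole days.
One record per patient: the earliest mGFR date, same-date ties broken by
file order (stable). Filters log per-rule exclusion counts and are
idempotent. Creatinine is converted to mg/dL on ingest (88.42 µmol/L per
mg/dL); malformed rows are collected with reasons, never silently dropped.

All quantiles — cohort summaries, residual IQR — use linear interpolation
between order statistics (the "type 7" convention, numpy's default).
Summary SD is the population SD so a single-record cohort reports 0 rather
than a missing value.

## Evaluation statistics

Residual: `mGFR − eGFR` in absolute mL/min. Bias = median residual;
precision = residual IQR; accuracy = RMSE; 1-P20 = proportion with
`|eGFR − mGFR|/mGFR` strictly greater than 0.20 (an APE of exactly 20% does
not count). Confidence intervals: bootstrap resampling of patients, default
2000 repetitions, normal approximation `estimate ± z₀.₉₇₅ · SD(bootstrap
statistics)`. The normal approximation can place an interval asymmetrically
around a skewed bootstrap distribution; by construction it is always
centred on the point estimate.

Model comparisons are paired: each repetition draws one patient resample and
evaluates both models on it, so the difference distribution respects the
strong correlation between models evaluated on the same patients. The P
value is two-sided by default (configurable), from the normal approximation
of the bootstrap difference; a model compared with itself yields delta 0 and
P = 1 (the 0/0 z-score is resolved by convention). Unpaired comparison is
deliberately not offered.

Subgroups default to cohort quartiles for continuous variables and
categories as-is for discrete ones; explicit bin edges override. The
matched-draw comparison matches each flagged patient 1:1 without replacement
to an unflagged patient of identical sex and nearest age within ±2 years
(ties broken randomly), then compares BSA, measured GFR and creatinine with
a Wilcoxon rank-sum test; both the tolerance and the test (rank-sum or Welch
t) are configurable since neither choice is canonical. Unmatchable patients
are counted and flag the draw rather than failing it.

## Synthetic cohort generator

The generator emulates a seven-center adult cohort of 3786
creatinine/measured-GFR pairs. What it reproduces:

- **Strata, exactly.** The published categorical table fixes, per center,
  the diagnosis-group counts plus female and black totals. The full
  center × diagnosis × sex × race table is completed deterministically by
  largest-remainder apportionment (female counts spread over diagnosis cells
  proportionally, then black counts over the diagnosis × sex cells), so all
  published margins — and the 3786 total — are exact.
- **Continuous marginals, in distribution.** Age ~ truncated normal
  (mean 57, SD 16, bounds 18–91 y). Height and weight are per-sex truncated
  normals (M 175.5±7.5 / F 161.5±7.0 cm; M 80±17 / F 68±15 kg) coupled by a
  shared per-person size factor giving a height–weight correlation ≈ 0.5;
  only the marginals are published, so the joint is a modeling choice.
  Parameters were set so cohort medians land on 169 cm / 74 kg / BSA 1.85 m².
- **The GFR–creatinine link, truth-first.** Latent true GFR ~ truncated
  normal, mean 86 mL/min, bounds 9–209. The *latent* SD is 36 mL/min: bound
  truncation and the feasibility redraw (below) compress the realized spread,
  and 36 is the value at which the realized mGFR SD matches the published
  32 mL/min. Noiseless creatinine is obtained by inverting the truth model's
  strictly decreasing creatinine→eGFR map (80-step vectorized bisection on
  [0.20, 4.5] mg/dL, converged far below measurement resolution). Draws whose
  GFR is unattainable within the creatinine bounds for the drawn demographics
  (mostly very high GFR in elderly, small patients) are redrawn, up to a
  bounded retry count — which induces a mild, realistic negative age–GFR
  dependence. The default truth model is CKD-EPI because its coefficients are
  fully published; any registered model can be substituted (Mayo cannot
  represent GFR above its clamp value, so it inverts only on part of the range).
- **Measurement error and assay calibration.** Creatinine gets multiplicative
  lognormal noise (σ = 0.06, a typical combined assay/biological CV), a
  global assay factor (default 1.010, set once so the default cohort's median
  creatinine lands on the published 0.95 mg/dL — laboratory creatinine not
  calibrated to the mass-spectrometry standard reads systematically high),
  and optional per-center factors emulating intercenter assay variability.
  Measured GFR gets additive normal noise (SD 5 mL/min, typical single-tracer
  clearance repeatability). Creatinine and mGFR errors are independent — the
  true dependence structure is unknown, and independence is the assumption.
  Out-of-bound noisy values are redrawn (bounded), then clipped to the
  inclusive bounds, so generated cohorts always pass the inclusion filters
  with zero exclusions.
- **Dates.** mGFR dates uniform over a five-year window; creatinine same-day
  with probability 0.27, otherwise offset uniformly within ±30 days. This
  matches a same-day fraction loosely, not the full offset distribution.

Randomness: one root seed per run, split hierarchically (demographics, GFR,
noise, dates) via seed sequences, so adding draws to one stage does not
perturb the others; the seed is echoed in the config and run manifests.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: real creatinine–GFR biology (creatinine is derived
*from* the truth model, so the truth model is correct by construction and
every accuracy ranking on synthetic data reflects distance from that
assumption, not clinical truth); per-center demographic differences beyond
the strata table (all centers share the same continuous marginals);
non-Gaussian tails in GFR (heavier-tailed alternatives were rejected for
testability); longitudinal/treatment effects; and the published per-center
creatinine distributions (center bias factors are a qualitative emulation).

## Problem sizes and determinism in the test suite

Unit tests run the generator at 200–1200 records (largest-remainder-scaled
strata) and the calibration/rank-recovery checks at 2000–3786; the bootstrap
coverage check uses 200 simulations of n = 500 at 2000 repetitions. These
sizes give stable verdicts at fixed seeds. All stochastic tests are seeded;
hypothesis property tests run with fixed example budgets.

## Known limitations

- CamGFR stand-in coefficients (above): rankings involving `camgfr` describe
  the stand-in, not the published model.
- The Martin entry is transcribed from its primary reference's widely
  reproduced form; verify `source_ref` before regulatory use.
- The age marginal is a symmetric truncated normal matched to the published
  mean/SD/range; it cannot simultaneously reproduce the published median
  (60 y > mean 57 y, i.e. the real distribution is left-skewed).
- Bootstrap CIs use the normal approximation throughout (matching the
  evaluation design being emulated); percentile intervals are not offered.
- 1-P20 treats measured GFR as the error-free denominator, as the metric's
  definition requires, although measured GFR itself carries noise.
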