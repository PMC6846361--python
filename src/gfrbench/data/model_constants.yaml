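# Coefficient registry for the serum-creatinine GFR/CrCl estimation models.
#
# Every formula kernel in gfrbench.models consumes only the named constants
# below, so a user can re-point gfrbench.models.load_constants() at an edited
# copy of this file (e.g. to flip jelliffe's native_scale to absolute_ml_min,
# or to substitute an updated coefficient set) without touching code.
#
# native_scale: absolute_ml_min | normalized_ml_min_173
# creatinine_unit: unit the ORIGINAL publication expressed creatinine in;
#   kernels always receive mg/dL and convert internally where needed.

models:
  cockcroft_gault:
    native_scale: absolute_ml_min
    creatinine_unit: mg_dl
    source_ref: "Cockcroft DW, Gault MH. Prediction of creatinine clearance from serum creatinine. Nephron 1976;16:31-41."
    coefficients:
      age_offset: 140.0
      denominator: 72.0
      female_factor: 0.85

  jelliffe:
    native_scale: normalized_ml_min_173
    creatinine_unit: mg_dl
    source_ref: "Jelliffe RW. Creatinine clearance: bedside estimate. Ann Intern Med 1973;79:604-605."
    coefficients:
      intercept: 98.0
      age_slope: 0.8
      age_offset: 20.0
      female_factor: 0.9

  mdrd186:
    native_scale: normalized_ml_min_173
    creatinine_unit: mg_dl
    source_ref: "Levey AS et al. A more accurate method to estimate glomerular filtration rate from serum creatinine (MDRD). Ann Intern Med 1999;130:461-470."
    coefficients:
      scale: 186.0
      creatinine_exp: -1.154
      age_exp: -0.203
      female_factor: 0.742
      black_factor: 1.212

  ckd_epi:
    native_scale: normalized_ml_min_173
    creatinine_unit: mg_dl
    source_ref: "Levey AS et al. A new equation to estimate glomerular filtration rate (CKD-EPI). Ann Intern Med 2009;150:604-612."
    coefficients:
      scale: 141.0
      kappa_female: 0.7
      kappa_male: 0.9
      alpha_female: -0.329
      alpha_male: -0.411
      beta: -1.209
      age_base: 0.993
      female_factor: 1.018
      black_factor: 1.159

  mayo:
    native_scale: normalized_ml_min_173
    creatinine_unit: mg_dl
    source_ref: "Rule AD et al. Using serum creatinine to estimate glomerular filtration rate: accuracy in good health and in chronic kidney disease (Mayo quadratic). Ann Intern Med 2004;141:929-937."
    coefficients:
      intercept: 1.911
      inv_creatinine: 5.249
      inv_creatinine_sq: -2.114
      age_slope: -0.00686
      female_term: -0.205
      creatinine_clamp: 0.8

  wright:
    native_scale: absolute_ml_min
    creatinine_unit: umol_l
    source_ref: "Wright JG et al. Estimation of glomerular filtration rate in cancer patients. Br J Cancer 2001;84:452-459."
    coefficients:
      intercept: 6580.0
      age_slope: 38.8
      female_reduction: 0.168

  martin:
    native_scale: absolute_ml_min
    creatinine_unit: umol_l
    source_ref: "Martin L et al. Improvement of the Cockcroft-Gault equation for predicting glomerular filtration in cancer patients. Bull Cancer 1998;85:631-636."
    coefficients:
      scale: 163.0
      age_slope: 0.00496
      female_reduction: 0.252

  camgfr:
    native_scale: absolute_ml_min
    creatinine_unit: mg_dl
    source_ref: "SYNTHETIC STAND-IN coefficients: published square-root-scale functional form (linear predictor in age, BSA, creatinine terms, sex; absolute output), coefficients calibrated by least squares against CKD-EPI-denormalized estimates over a realistic adult covariate grid because the original coefficient table is not reproduced here. Replace via load_constants(path) to use the published values."
    coefficients:
      intercept: 6.76833
      age_slope: -0.02964
      bsa_slope: 2.26343
      log_creatinine_slope: -3.12806
      creatinine_slope: -0.28978
      female_term: -0.83556
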