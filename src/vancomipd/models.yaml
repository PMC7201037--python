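# Population PK model catalog (catalog_version 1.0).
# Constants and variance components of the published vancomycin models the
# dosing engine supports.  Editing this file (not code) is the supported way
# to revise a model's parameters.
catalog_version: "1.0"
models:
  frymoyer_neonatal:
    n_compartments: 1
    structure:
      # CL = cl_std * (Wt/wt_ref)^cl_wt_exp * (cr_ref/Cr)^cr_exp * sigmoid(PMA)
      # sigmoid(PMA) = 1 / (1 + (PMA/pma50)^-hill)
      cl_std: 0.345          # L/h at the reference covariates
      wt_ref: 2.9            # kg
      cl_wt_exp: 0.75
      cr_ref: 1.0            # mg/dL
      cr_exp: 0.267
      pma50: 34.8            # weeks, PMA of half-maximal maturation
      hill: 4.53
      v_std: 1.75            # L at wt_ref, scales linearly with weight
    iiv_cv: {CL: 21.6, V: 10.9}
    residual_proportional_cv: 20.5
    residual_additive_sd: 1.3   # mg/L
  le_pediatric:
    n_compartments: 1
    structure:
      # CL = cl_std * Wt^cl_wt_exp * (cr_ref/Cr)^cr_exp * (ln(Age_d)/lnage_ref)^age_exp
      cl_std: 0.248          # L/h/kg^0.75
      cl_wt_exp: 0.75
      cr_ref: 0.48           # mg/dL
      cr_exp: 0.361
      lnage_ref: 7.8         # ln(days)
      age_exp: 0.995
      v_per_kg: 0.636        # L/kg
    iiv_cv: {CL: 35.0, V: 18.0}
    residual_proportional_cv: 29.0
    residual_additive_sd: 0.0
  thomson:
    n_compartments: 2
    structure:
      # CL = cl_std * (1 + crcl_slope * (CrCl - crcl_ref))
      cl_std: 2.99           # L/h
      crcl_slope: 0.0154     # per ml/min
      crcl_ref: 66.0         # ml/min
      v1_per_kg: 0.675       # L/kg
      v2_per_kg: 0.732       # L/kg
      q: 2.28                # L/h (not weight-scaled, as published)
    iiv_cv: {CL: 27.0, V1: 15.0, V2: 130.0, Q: 149.0}
    residual_proportional_cv: 15.0
    residual_additive_sd: 1.6   # mg/L
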