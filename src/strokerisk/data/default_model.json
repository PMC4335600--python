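{
  "model_name": "riskometer",
  "sex_specific": {
    "male": {
      "betas": {
        "age": 0.0505,
        "sbp": 0.014,
        "antihypertensive_treatment": 0.3263,
        "diabetes": 0.3384,
        "current_smoker": 0.5147,
        "cvd_history": 0.5212,
        "atrial_fibrillation": 0.6108,
        "lvh": 0.7778
      },
      "covariate_means": {
        "age": 64.9,
        "sbp": 139.0,
        "antihypertensive_treatment": 0.26,
        "diabetes": 0.09,
        "current_smoker": 0.27,
        "cvd_history": 0.21,
        "atrial_fibrillation": 0.02,
        "lvh": 0.04
      },
      "baseline_survival": {"10": 0.945},
      "reference_sbp": 120.0,
      "provenance": "Approximate transcription of the published Framingham stroke probability equations (Cox form, 10-year baseline survival; 5-year derived under a constant baseline hazard). Shipped as a convenience default only - verify against the original publication before any substantive use."
    },
    "female": {
      "betas": {
        "age": 0.0665,
        "sbp": 0.0138,
        "antihypertensive_treatment": 0.43,
        "diabetes": 0.387,
        "current_smoker": 0.5922,
        "cvd_history": 0.461,
        "atrial_fibrillation": 0.841,
        "lvh": 0.434
      },
      "covariate_means": {
        "age": 66.1,
        "sbp": 137.0,
        "antihypertensive_treatment": 0.31,
        "diabetes": 0.08,
        "current_smoker": 0.24,
        "cvd_history": 0.11,
        "atrial_fibrillation": 0.03,
        "lvh": 0.03
      },
      "baseline_survival": {"10": 0.965},
      "reference_sbp": 120.0,
      "provenance": "Approximate transcription of the published Framingham stroke probability equations (Cox form, 10-year baseline survival; 5-year derived under a constant baseline hazard). Shipped as a convenience default only - verify against the original publication before any substantive use."
    }
  },
  "deltas": {
    "lp_deltas": {
      "non_caucasian": 0.2,
      "poor_diet": 0.2,
      "high_alcohol": 0.1,
      "low_physical_activity": 0.1,
      "family_history": 0.05,
      "stress": 0.0
    },
    "rr_multipliers": {
      "cognitive_problems": 1.8,
      "memory_only": 1.4,
      "previous_tbi": 1.2
    },
    "prior_stroke_percent_points": {"5": 10.0, "10": 15.0}
  }
}
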