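{
  "version": "1.0",
  "description": "Published coefficient sets for the UKPDS and Framingham CHD risk equations. Treated as immutable; loaded once per process.",
  "ukpds": {
    "log_q_intercept": -4.4918,
    "d": 1.078,
    "coefficients": {
      "age": 0.0573,
      "female": -0.6444,
      "afro_caribbean": -0.9416,
      "smoker": 0.3001,
      "hba1c": 0.1681,
      "sbp_per_10mmhg": 0.0843,
      "ln_tc_hdl": 1.3468
    },
    "centers": {
      "age": 55.0,
      "hba1c": 6.72,
      "sbp": 135.7,
      "ln_tc_hdl": 1.59
    }
  },
  "framingham_initial": {
    "male": {
      "intercept": -3.0975,
      "age": 0.0483,
      "age_squared": 0.0,
      "tc": {
        "lt160": -0.6595,
        "160_199": 0.0,
        "200_239": 0.1769,
        "240_279": 0.5054,
        "ge280": 0.6571
      },
      "hdl": {
        "lt35": 0.4974,
        "35_44": 0.2431,
        "45_49": 0.0,
        "50_59": -0.0511,
        "ge60": -0.4866
      },
      "bp": {
        "optimal": -0.0023,
        "normal": 0.0,
        "high_normal": 0.2832,
        "stage1": 0.5217,
        "stage2_4": 0.6186
      },
      "diabetes": 0.4284,
      "smoker": 0.5234,
      "baseline_survival": {
        "1": 0.9946,
        "2": 0.985,
        "3": 0.977,
        "4": 0.9622,
        "5": 0.95592
      }
    },
    "female": {
      "intercept": -9.9255,
      "age": 0.3377,
      "age_squared": -0.0027,
      "tc": {
        "lt160": -0.2614,
        "160_199": 0.0,
        "200_239": 0.2077,
        "240_279": 0.2439,
        "ge280": 0.5351
      },
      "hdl": {
        "lt35": 0.8431,
        "35_44": 0.378,
        "45_49": 0.1979,
        "50_59": 0.0,
        "ge60": -0.4295
      },
      "bp": {
        "optimal": -0.5336,
        "normal": 0.0,
        "high_normal": -0.0677,
        "stage1": 0.2629,
        "stage2_4": 0.4657
      },
      "diabetes": 0.5963,
      "smoker": 0.2925,
      "baseline_survival": {
        "1": 0.9984,
        "2": 0.9933,
        "3": 0.9909,
        "4": 0.9858,
        "5": 0.98297
      }
    }
  },
  "framingham_secondary": {
    "male": {
      "intercept": 4.995,
      "age": -0.0145,
      "ln_tc_hdl": -0.6738,
      "ln_sbp": 0.0,
      "diabetes": -0.3042,
      "smoker": 0.0,
      "sigma": 0.9994
    },
    "female": {
      "intercept": 13.537,
      "age": -0.0225,
      "ln_tc_hdl": -0.834,
      "ln_sbp": -1.3713,
      "diabetes": -0.7829,
      "smoker": -0.3669,
      "sigma": 1.0313
    }
  }
}
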