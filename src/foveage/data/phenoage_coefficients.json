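{
  "version": "levine-2018-v1",
  "description": "Mortality-score regression weights and Gompertz constants for the PhenoAge phenotypic-age algorithm (nine blood biomarkers plus chronological age), transcribed from the published coefficient table.",
  "units": {
    "albumin": "g/L",
    "creatinine": "umol/L",
    "glucose": "mmol/L",
    "crp": "mg/L stored; enters the linear predictor as ln(mg/dL) = ln(mg_L/10)",
    "lymphocyte_pct": "%",
    "mcv": "fL",
    "rdw": "%",
    "alp": "U/L",
    "wbc": "1e9 cells/L",
    "chron_age": "years"
  },
  "linear_predictor": {
    "intercept": -19.907,
    "albumin": -0.0336,
    "creatinine": 0.0095,
    "glucose": 0.1953,
    "log_crp_mg_dl": 0.0954,
    "lymphocyte_pct": -0.012,
    "mcv": 0.0268,
    "rdw": 0.3306,
    "alp": 0.00188,
    "wbc": 0.0554,
    "chron_age": 0.0804
  },
  "gompertz": {
    "gamma": 0.0076927,
    "horizon_months": 120
  },
  "age_mapping": {
    "offset_years": 141.50225,
    "rate_per_year": 0.09165,
    "scale": 0.00553
  }
}
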