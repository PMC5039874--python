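{
  "strategies": {
    "intervention": {
      "name": "TMZ+SoC",
      "monthly_drug_cost": 29.18,
      "transition_matrix": {
        "minimal": {
          "minimal": 0.9465648854961832,
          "mild": 0.04198473282442748,
          "moderate": 0.011450381679389313,
          "severe": 0.0
        },
        "mild": {
          "minimal": 0.5271739130434783,
          "mild": 0.41304347826086957,
          "moderate": 0.05434782608695652,
          "severe": 0.005434782608695652
        },
        "moderate": {
          "minimal": 0.1941747572815534,
          "mild": 0.6116504854368932,
          "moderate": 0.1553398058252427,
          "severe": 0.038834951456310676
        },
        "severe": {
          "minimal": 0.14285714285714285,
          "mild": 0.18095238095238095,
          "moderate": 0.24761904761904763,
          "severe": 0.42857142857142855
        }
      }
    },
    "comparator": {
      "name": "SoC",
      "monthly_drug_cost": 23.4,
      "transition_matrix": {
        "minimal": {
          "minimal": 0.9060773480662984,
          "mild": 0.09392265193370165,
          "moderate": 0.0,
          "severe": 0.0
        },
        "mild": {
          "minimal": 0.46596858638743455,
          "mild": 0.418848167539267,
          "moderate": 0.09424083769633508,
          "severe": 0.020942408376963352
        },
        "moderate": {
          "minimal": 0.25842696629213485,
          "mild": 0.43820224719101125,
          "moderate": 0.23595505617977527,
          "severe": 0.06741573033707865
        },
        "severe": {
          "minimal": 0.1171875,
          "mild": 0.265625,
          "moderate": 0.15625,
          "severe": 0.4609375
        }
      }
    }
  },
  "annual_mortality": {
    "minimal": 0.046,
    "mild": 0.048,
    "moderate": 0.081,
    "severe": 0.109
  },
  "utilities": {
    "minimal": 0.81,
    "mild": 0.75,
    "moderate": 0.6,
    "severe": 0.39
  },
  "baseline": {
    "minimal": 0.0,
    "mild": 0.46938775510204084,
    "moderate": 0.2627551020408163,
    "severe": 0.26785714285714285
  },
  "state_costs": {
    "outpatient_visits": {
      "minimal": 8.0,
      "mild": 15.75,
      "moderate": 39.88,
      "severe": 76.5
    },
    "diagnostic_tests": {
      "minimal": 41.62,
      "mild": 62.05,
      "moderate": 101.0,
      "severe": 122.37
    },
    "laboratory_tests": {
      "minimal": 20.41,
      "mild": 25.63,
      "moderate": 45.31,
      "severe": 61.24
    },
    "hosp_no_revasc": {
      "minimal": 4.67,
      "mild": 35.03,
      "moderate": 331.06,
      "severe": 1428.63
    },
    "hosp_revasc": {
      "minimal": 586.24,
      "mild": 683.62,
      "moderate": 1583.23,
      "severe": 1972.77
    }
  },
  "n_cycles": 4,
  "cycle_length_years": 0.25,
  "wtp_threshold": 34000.0,
  "discount_rate": 0.0,
  "metadata": {
    "currency": "EUR2016",
    "description": "TMZ 70 mg/d add-on vs standard of care, Greece",
    "transition_row_n": {
      "TMZ+SoC": [
        262,
        184,
        103,
        105
      ],
      "SoC": [
        181,
        191,
        89,
        128
      ]
    },
    "baseline_n": 392
  }
}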