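{
  "type": "object",
  "required": ["options", "chemicals", "contrasts"],
  "properties": {
    "options": {
      "type": "object",
      "required": ["weighting_exponent", "qc", "target_temperature_C", "vanthoff_temperatures_C"],
      "properties": {
        "weighting_exponent": {"type": "integer", "enum": [0, 1, 2]},
        "qc": {"type": "boolean"},
        "target_temperature_C": {"type": "number"},
        "vanthoff_temperatures_C": {"type": "array", "items": {"type": "number"}}
      }
    },
    "chemicals": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["direct_fits", "direct_target", "vanthoff", "indirect_target", "volatility_class", "direct_minus_indirect"],
        "properties": {
          "direct_fits": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["temperature_C", "kaw", "kaw_ci95", "amplitude", "r_squared", "n_used", "excluded_ratios", "converged", "reportable", "log10_kaw", "log10_kaw_ci95"],
              "properties": {
                "temperature_C": {"type": "number"},
                "kaw": {"type": "number"},
                "kaw_ci95": {"type": "array", "items": {"type": "number"}},
                "amplitude": {"type": "number"},
                "r_squared": {"type": "number"},
                "n_used": {"type": "integer"},
                "excluded_ratios": {"type": "array", "items": {"type": "number"}},
                "converged": {"type": "boolean"},
                "reportable": {"type": "boolean"},
                "log10_kaw": {"type": "number", "nullable": true},
                "log10_kaw_ci95": {"type": "array", "items": {"type": "number"}, "nullable": true}
              }
            }
          },
          "direct_target": {
            "type": "object",
            "nullable": true,
            "required": ["log10_kaw", "ci95"],
            "properties": {
              "log10_kaw": {"type": "number"},
              "ci95": {"type": "array", "items": {"type": "number"}}
            }
          },
          "vanthoff": {
            "type": "object",
            "nullable": true,
            "required": ["slope", "slope_ci95", "intercept", "r_squared", "delta_u", "delta_u_ci95", "n_points", "temperatures_C"],
            "properties": {
              "slope": {"type": "number"},
              "slope_ci95": {"type": "array", "items": {"type": "number"}},
              "intercept": {"type": "number"},
              "r_squared": {"type": "number"},
              "delta_u": {"type": "number"},
              "delta_u_ci95": {"type": "array", "items": {"type": "number"}},
              "n_points": {"type": "integer"},
              "temperatures_C": {"type": "array", "items": {"type": "number"}}
            }
          },
          "indirect_target": {
            "type": "object",
            "nullable": true,
            "required": ["log10_kaw", "ci95", "extrapolated"],
            "properties": {
              "log10_kaw": {"type": "number"},
              "ci95": {"type": "array", "items": {"type": "number"}},
              "extrapolated": {"type": "boolean"}
            }
          },
          "volatility_class": {
            "type": "string",
            "nullable": true,
            "enum": ["nonvolatile", "semivolatile", "volatile"]
          },
          "direct_minus_indirect": {"type": "number", "nullable": true}
        }
      }
    },
    "contrasts": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["pair", "per_condition", "mean_abs", "max_abs"],
        "properties": {
          "pair": {"type": "array", "items": {"type": "string"}},
          "per_condition": {"type": "object", "additionalProperties": {"type": "number"}},
          "mean_abs": {"type": "number"},
          "max_abs": {"type": "number"}
        }
      }
    },
    "predictions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["chemical", "model", "log10_kaw_predicted", "in_domain", "delta_vs_direct", "delta_vs_indirect"],
        "properties": {
          "chemical": {"type": "string"},
          "model": {"type": "string"},
          "log10_kaw_predicted": {"type": "number"},
          "in_domain": {"type": "boolean"},
          "delta_vs_direct": {"type": "number", "nullable": true},
          "delta_vs_indirect": {"type": "number", "nullable": true}
        }
      }
    }
  }
}
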