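{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "uwcager pipeline summary",
  "type": "object",
  "required": [
    "a0", "a1", "b0", "b1",
    "crit_area_cm2", "crit_perimeter_cm", "closure_day",
    "n_events", "n_sharks", "class_counts",
    "validation", "month_histogram", "seasonality"
  ],
  "properties": {
    "a0": {"type": "number"},
    "a1": {"type": "number"},
    "b0": {"type": "number"},
    "b1": {"type": "number"},
    "crit_area_cm2": {"type": "number"},
    "crit_perimeter_cm": {"type": "number"},
    "closure_day": {"type": "integer"},
    "n_events": {"type": "integer"},
    "n_sharks": {"type": "integer"},
    "class_counts": {
      "type": "object",
      "additionalProperties": {"type": "integer"}
    },
    "validation": {
      "type": "object",
      "required": ["n", "mean_abs_diff", "sd_abs_diff", "n_excluded"],
      "properties": {
        "n": {"type": "integer"},
        "mean_abs_diff": {"type": ["number", "null"]},
        "sd_abs_diff": {"type": ["number", "null"]},
        "n_excluded": {"type": "integer"}
      }
    },
    "month_histogram": {
      "type": "object",
      "additionalProperties": {"type": "integer"}
    },
    "seasonality": {
      "type": "object",
      "required": ["chi2", "df", "p_value", "n_outside_window"],
      "properties": {
        "chi2": {"type": ["number", "null"]},
        "df": {"type": ["integer", "null"]},
        "p_value": {"type": ["number", "null"]},
        "n_outside_window": {"type": "integer"}
      }
    },
    "morphometrics": {
      "type": "object",
      "required": ["response", "f_stat", "df", "p_value"]
    }
  }
}
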