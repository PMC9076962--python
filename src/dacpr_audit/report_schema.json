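{
  "type": "object",
  "required": ["provenance", "registry_context", "cascade", "goals", "overall_survival", "lives_saved", "curves"],
  "properties": {
    "provenance": {
      "type": "object",
      "required": ["tool_version", "config"],
      "properties": {
        "tool_version": {"type": "string"},
        "config": {"type": "object"}
      }
    },
    "registry_context": {
      "type": "object",
      "required": ["national_ohca", "excluded_not_available", "excluded_ems_witnessed", "excluded_regional_emdc", "eligible", "sampled"]
    },
    "cascade": {
      "type": "object",
      "required": ["n_input", "n_included", "study_exclusions", "n_recognizable", "recognizability_exclusions", "n_recognized", "n_dacpr_available", "dacpr_exclusions"],
      "properties": {
        "n_input": {"type": "integer"},
        "n_included": {"type": "integer"},
        "study_exclusions": {"type": "object", "required": ["ALIVE_DURING_CALL", "MISSING_AUDIO"]},
        "n_recognizable": {"type": "integer"},
        "recognizability_exclusions": {"type": "object", "required": ["CPR_IN_PROGRESS", "THIRD_PARTY", "HYSTERICAL", "HANG_UP", "LANGUAGE", "OTHER"]},
        "n_recognized": {"type": "integer"},
        "n_dacpr_available": {"type": "integer"},
        "dacpr_exclusions": {"type": "object", "required": ["CANNOT_MOVE", "REFUSES", "HANG_UP", "NOT_WITH_PATIENT", "OTHER"]}
      }
    },
    "goals": {
      "type": "object",
      "required": ["goal1", "goal2", "goal3", "goal3_any_compression", "goal4", "goal4_dispatch", "goal5", "goal5_any_compression", "goal5_instructions"],
      "properties": {
        "goal1": {"type": "object", "required": ["numerator", "denominator", "pct", "pct_rounded", "target_pct", "met"]},
        "goal2": {"type": "object", "required": ["numerator", "denominator", "pct", "pct_rounded", "target_pct", "met"]},
        "goal3": {"type": "object", "required": ["numerator", "denominator", "pct", "pct_rounded", "target_pct", "met"]},
        "goal3_any_compression": {"type": "object", "required": ["numerator", "denominator", "pct", "pct_rounded", "target_pct", "met"]},
        "goal4": {"type": "object", "required": ["variable", "n_with_time", "n_missing", "denominator", "median_s", "q1_s", "q3_s", "attainment", "high_perf_s", "minimal_std_s", "met_high", "met_minimal"]},
        "goal4_dispatch": {"type": "object", "required": ["variable", "median_s", "attainment", "met_high", "met_minimal"]},
        "goal5": {"type": "object", "required": ["variable", "n_with_time", "n_missing", "denominator", "median_s", "q1_s", "q3_s", "attainment", "high_perf_s", "minimal_std_s", "met_high", "met_minimal"]},
        "goal5_any_compression": {"type": "object", "required": ["variable", "median_s", "attainment", "met_high", "met_minimal"]},
        "goal5_instructions": {"type": "object", "required": ["variable", "median_s", "attainment"]}
      }
    },
    "overall_survival": {
      "type": "object",
      "required": ["survivors", "n_known", "denominator", "pct", "pct_rounded"],
      "properties": {
        "survivors": {"type": "integer"},
        "n_known": {"type": "integer"},
        "denominator": {"type": "integer"},
        "pct": {"type": ["number", "null"]},
        "pct_rounded": {"type": ["integer", "null"]}
      }
    },
    "lives_saved": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["target", "stage", "time_field", "threshold_s"]
      }
    },
    "curves": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["variable", "n_complete"]
      }
    }
  }
}
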