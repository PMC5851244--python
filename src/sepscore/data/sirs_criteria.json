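{
  "_comment": "SIRS component criteria, 1992 consensus definitions. Strict inequalities throughout: boundary values do not score.",
  "temperature": {"input": "temp", "units": "degC", "high": 38.0, "low": 36.0},
  "heart_rate": {"input": "hr", "units": "beats/min", "high": 90.0},
  "respiratory": {
    "input": "rr_or_paco2",
    "rr_high": 20.0,
    "rr_units": "breaths/min",
    "paco2_low": 32.0,
    "paco2_units": "mmHg"
  },
  "white_cells": {"input": "wbc", "units": "10^3/uL", "high": 12.0, "low": 4.0}
}
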