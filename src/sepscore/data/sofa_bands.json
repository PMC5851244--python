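{
  "_comment": "SOFA organ-system point bands, 1996 consensus definitions. Each band is [threshold, points]; direction says whether lower or higher measured values are more abnormal. Respiration bands are applied on PaO2/FiO2 alone (ventilatory-support qualifier not applied; see docs/methods.md). Urine-output renal criteria intentionally absent.",
  "respiration": {
    "input": "pf_ratio",
    "units": "mmHg",
    "direction": "lower_worse",
    "bands": [[100, 4], [200, 3], [300, 2], [400, 1]]
  },
  "coagulation": {
    "input": "platelets",
    "units": "10^3/uL",
    "direction": "lower_worse",
    "bands": [[20, 4], [50, 3], [100, 2], [150, 1]]
  },
  "liver": {
    "input": "bilirubin",
    "units": "mg/dL",
    "direction": "higher_worse",
    "bands": [[12.0, 4], [6.0, 3], [2.0, 2], [1.2, 1]]
  },
  "cardiovascular": {
    "input": "map_or_vasopressor",
    "units": "mmHg / dose class",
    "map_hypotension_threshold": 70,
    "vasopressor_points": {
      "NONE": 0,
      "DOPA_LOW": 2,
      "DOPA_MID_OR_ANY_NE_LOW": 3,
      "DOPA_HIGH_OR_NE_HIGH": 4
    }
  },
  "cns": {
    "input": "mental",
    "units": "AVPU level",
    "avpu_points": {"ALERT": 0, "VERBAL": 1, "PAIN": 3, "UNRESPONSIVE": 4},
    "gcs_anchors": {"ALERT": 15, "VERBAL": 13, "PAIN": 8, "UNRESPONSIVE": 3}
  },
  "renal": {
    "input": "creatinine",
    "units": "mg/dL",
    "direction": "higher_worse",
    "bands": [[5.0, 4], [3.5, 3], [2.0, 2], [1.2, 1]]
  }
}
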