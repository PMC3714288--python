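{
  "description": "Categorical coronary-risk point system for women (total-cholesterol version): integer points for age, total cholesterol, HDL-C, blood pressure (joint SBP x DBP classification), diabetes and smoking, summed to a single score. Reconstructed from the published categorical point-assignment system; when SBP and DBP fall in discordant pressure categories the higher-risk category governs the lookup.",
  "provenance": "Women's point-score sheet of the categorical Framingham risk-factor scoring system (total cholesterol variant). Encoded by hand; category bounds in the units noted per factor. Manual-lookup fixture recorded below.",
  "units": {"age": "years", "total_cholesterol": "mg/dL", "hdl": "mg/dL", "sbp": "mm Hg", "dbp": "mm Hg"},
  "age": {
    "bounds": [30, 35, 40, 45, 50, 55, 60, 65, 70, 75],
    "points": [-9, -4, 0, 3, 6, 7, 8, 8, 8]
  },
  "total_cholesterol": {
    "bounds": [100, 160, 200, 240, 280, 1000],
    "points": [-2, 0, 1, 2, 3]
  },
  "hdl": {
    "bounds": [5, 35, 45, 50, 60, 1000],
    "points": [5, 2, 1, 0, -2]
  },
  "blood_pressure": {
    "categories": ["optimal", "normal", "high_normal", "stage1", "stage2plus"],
    "sbp_bounds": [50, 120, 130, 140, 160, 400],
    "dbp_bounds": [30, 80, 85, 90, 100, 250],
    "points": [-3, 0, 1, 2, 3],
    "rule": "classify SBP and DBP separately; the higher-risk (larger-point) category governs"
  },
  "smoker": {"points": 2},
  "diabetes": {"points": 4},
  "fixture": {
    "inputs": {"age": 53, "total_cholesterol": 208, "hdl": 72, "sbp": 117, "dbp": 75, "smoker": 0, "diabetic": 0},
    "lookup": {"age": 6, "total_cholesterol": 1, "hdl": -2, "blood_pressure": -3, "smoker": 0, "diabetes": 0},
    "total": 2
  }
}
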