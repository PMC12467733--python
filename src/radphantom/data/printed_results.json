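{
  "comment": "Published summary values regenerated by the fixture pipeline. Entries in known_artifacts differ from a recomputation because the published per-row inputs are themselves rounded to 2 dp; they are compared at +/-0.01 instead of at printed precision.",
  "system_summaries": {
    "Eagle Eye": {"mae": 8.05, "rmse": 9.31, "bias": -2.03, "sd": 9.09},
    "EOS": {"mae": 9.30, "rmse": 10.49, "bias": -0.34, "sd": 10.48},
    "UDR780IPRO3F": {"mae": 20.13, "rmse": 23.96, "bias": -20.13, "sd": 12.99},
    "GC85A": {"mae": 19.78, "rmse": 22.37, "bias": -19.78, "sd": 10.46},
    "DRX-Compass": {"mae": 19.23, "rmse": 23.46, "bias": -16.93, "sd": 16.24},
    "DSI-DRP": {"mae": 15.32, "rmse": 19.26, "bias": -15.32, "sd": 11.67}
  },
  "system_tests": {
    "Eagle Eye": {"normality_p": 0.358, "distribution": "Normal", "wilcoxon_p": 0.570, "t_p": 0.545},
    "EOS": {"normality_p": 0.712, "distribution": "Normal", "wilcoxon_p": 0.910, "t_p": 0.929},
    "UDR780IPRO3F": {"normality_p": 0.420, "distribution": "Normal", "wilcoxon_p": 0.004, "t_p": 0.002},
    "GC85A": {"normality_p": 0.298, "distribution": "Normal", "wilcoxon_p": 0.004, "t_p": 0.001},
    "DRX-Compass": {"normality_p": 0.434, "distribution": "Normal", "wilcoxon_p": 0.027, "t_p": 0.019},
    "DSI-DRP": {"normality_p": 0.008, "distribution": "Non-normal", "wilcoxon_p": 0.004, "t_p": null}
  },
  "group_descriptives": {
    "slot": {"n": 18, "mean": -1.19, "sd": 10.13, "median": -2.56, "q1": -9.63, "q3": 6.08},
    "rotational": {"n": 27, "mean": -18.95, "sd": 13.77, "median": -19.89, "q1": -29.98, "q3": -3.98},
    "one_shot": {"n": 9, "mean": -15.32, "sd": 12.38, "median": -11.87, "q1": -19.19, "q3": -7.77}
  },
  "omnibus": {"H": 15.86, "df": 2, "epsilon_sq": 0.272, "levene_p": 0.4988,
              "group_normality_p": {"slot": 0.2374, "rotational": 0.2003, "one_shot": 0.0079}},
  "dunn": {
    "slot_vs_rotational": {"mrd": 18.74, "ci": [7.31, 30.17], "p_adj": 0.0003},
    "slot_vs_one_shot": {"mrd": 15.44, "ci": [0.11, 30.78], "p_adj": 0.0478},
    "rotational_vs_one_shot": {"mrd": -3.30, "ci": [-17.75, 11.16], "p_adj": 0.9291}
  },
  "plane_calibrations": {
    "Eagle Eye": {"1": {"mean_diameter_mm": 9.69, "epsilon": 1.21}, "2": {"mean_diameter_mm": 9.58, "epsilon": 1.20}},
    "EOS": {"1": {"mean_diameter_mm": 7.96, "epsilon": 1.00}, "2": {"mean_diameter_mm": 7.86, "epsilon": 0.98}},
    "GC85A": {"1": {"mean_diameter_mm": 9.25, "epsilon": 1.16}, "2": {"mean_diameter_mm": 8.58, "epsilon": 1.07}},
    "UDR780IPRO3F": {"1": {"mean_diameter_mm": 10.04, "epsilon": 1.25}, "2": {"mean_diameter_mm": 9.52, "epsilon": 1.19}},
    "DRX-Compass": {"1": {"mean_diameter_mm": 11.90, "epsilon": 1.49}, "2": {"mean_diameter_mm": 11.53, "epsilon": 1.44}},
    "DSI-DRP": {"1": {"mean_diameter_mm": 8.69, "epsilon": 1.09}, "2": {"mean_diameter_mm": 8.55, "epsilon": 1.07}}
  },
  "circularity_summaries": {
    "Eagle Eye": {"mean": 0.60, "sd": 0.05},
    "EOS": {"mean": 0.61, "sd": 0.08},
    "UDR780IPRO3F": {"mean": 0.54, "sd": 0.04},
    "GC85A": {"mean": 0.59, "sd": 0.08},
    "DRX-Compass": {"mean": 0.36, "sd": 0.11},
    "DSI-DRP": {"mean": 0.60, "sd": 0.05}
  },
  "known_artifacts": [
    "system_summaries/Eagle Eye/mae",
    "system_summaries/EOS/sd",
    "system_tests/EOS/t_p",
    "system_tests/DRX-Compass/t_p",
    "plane_calibrations/Eagle Eye/2/mean_diameter_mm",
    "plane_calibrations/GC85A/2/mean_diameter_mm",
    "plane_calibrations/UDR780IPRO3F/1/mean_diameter_mm"
  ]
}
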