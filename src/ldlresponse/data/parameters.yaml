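# Published dose-response parameters for bempedoic acid, four statins and
# their combinations.  Effects are stored as the magnitude of the fractional
# LDL-C lowering (the source model reports them as negative proportional
# change from baseline); loaders negate nothing further.
#
# "se: null" marks a parameter fixed without uncertainty (FIX).

bempedoic_acid:
  monotherapy:
    baseline_ldl_mgdl: {estimate: 147.1, se: 1.1, ci95: [144.9, 149.3]}
    kout_per_h: {estimate: 0.01, se: null}
    emax: {estimate: 0.34, se: 0.01, ci95: [0.32, 0.36]}
    ed50_mg: {estimate: 44.0, se: 3.8, ci95: [36.6, 51.3]}
    hill: {estimate: 1.0, se: null}
    residual:
      proportional: {estimate: 0.084, ci95: [0.075, 0.093]}
      additive_mgdl: {estimate: 11.4, se: 0.6, ci95: [10.3, 12.5]}
    iiv_cv:
      baseline: {estimate: 0.230, ci95: [0.219, 0.241]}
      emax: {estimate: 0.362, ci95: [0.326, 0.394]}
  # Values fixed in the combination models.
  combination:
    emax: 0.34
    ed50_mg: 43.96
    hill: 1.0

statins:
  shared:
    emax: 0.787          # common maximal fractional lowering, fixed
    hill: 0.451          # common Hill coefficient, fixed

statin_profiles:
  atorvastatin:
    ed50_mg: 13.1
    max_label_dose_mg: 80
    dose_grid_mg: [10, 20, 40, 80]
    baseline_ldl_mgdl: {estimate: 177.9, ci95: [176.0, 179.7]}
    iiv_cv_baseline: {estimate: 0.271, ci95: [0.263, 0.278]}
    residual:
      proportional: {estimate: 0.161, ci95: [0.157, 0.165]}
      additive_mgdl: {estimate: 8.8, ci95: [8.1, 9.5]}
  simvastatin:
    ed50_mg: 30.5
    max_label_dose_mg: 40
    dose_grid_mg: [10, 20, 40]
    baseline_ldl_mgdl: {estimate: 160.4, ci95: [158.2, 162.5]}
    iiv_cv_baseline: {estimate: 0.255, ci95: [0.245, 0.265]}
    residual:
      proportional: {estimate: 0.135, ci95: [0.128, 0.143]}
      additive_mgdl: {estimate: 13.3, ci95: [12.3, 14.3]}
  rosuvastatin:
    ed50_mg: 4.4
    max_label_dose_mg: 40
    dose_grid_mg: [10, 20, 40]
    baseline_ldl_mgdl: {estimate: 171.9, ci95: [169.4, 174.6]}
    iiv_cv_baseline: {estimate: 0.304, ci95: [0.292, 0.314]}
    residual:
      proportional: {estimate: 0.151, ci95: [0.144, 0.157]}
      additive_mgdl: {estimate: 11.7, ci95: [10.6, 12.8]}
  pravastatin:
    ed50_mg: 97.3
    max_label_dose_mg: 80
    dose_grid_mg: [10, 20, 40, 80]
    baseline_ldl_mgdl: {estimate: 156.7, ci95: [154.5, 158.8]}
    iiv_cv_baseline: {estimate: 0.242, ci95: [0.231, 0.252]}
    residual:
      proportional: {estimate: 0.100, ci95: [0.089, 0.110]}
      additive_mgdl: {estimate: 17.9, ci95: [16.9, 18.9]}

interaction:
  gamma: -1.35           # common across statins, fixed

turnover:
  kout_per_h: 0.01       # fixed to a literature-consistent value
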