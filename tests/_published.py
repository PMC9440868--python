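"""Published reference predictions used as frozen expected values.

Percent-change cells are the reported simulation means (integer percent,
negative = lowering) for each statin dose alone and combined with bempedoic
acid 180 mg, plus the additional-lowering column; absolute cells are the
reported mean week-12 LDL-C (mg/dL) on the shared atorvastatin-model
baseline population.
"""

# (statin, dose) -> (alone %, + BA 180 %, delta %)
PCT_CHANGE = {
    ("atorvastatin", 10): (-37, -51, -22),
    ("atorvastatin", 20): (-43, -54, -19),
    ("atorvastatin", 40): (-49, -58, -18),
    ("atorvastatin", 80): (-54, -62, -17),
    ("simvastatin", 10): (-30, -46, -23),
    ("simvastatin", 20): (-36, -50, -22),
    ("simvastatin", 40): (-42, -54, -21),
    ("rosuvastatin", 10): (-46, -57, -20),
    ("rosuvastatin", 20): (-52, -60, -17),
    ("rosuvastatin", 40): (-57, -63, -14),
    ("pravastatin", 10): (-21, -41, -25),
    ("pravastatin", 20): (-26, -44, -24),
    ("pravastatin", 40): (-32, -47, -22),
    ("pravastatin", 80): (-38, -51, -21),
}

#: bempedoic acid 180 mg monotherapy mean percent change
BA_MONO_PCT = -27

# (statin, dose) -> (alone mg/dL, + BA 180 mg/dL); dose 0 = no statin
ABS_LDL = {
    ("atorvastatin", 0): (183.1, 132.7),
    ("atorvastatin", 10): (116.2, 89.6),
    ("atorvastatin", 20): (104.0, 84.0),
    ("atorvastatin", 40): (94.2, 77.5),
    ("atorvastatin", 80): (84.2, 70.6),
    ("simvastatin", 10): (129.0, 99.6),
    ("simvastatin", 20): (117.7, 92.5),
    ("simvastatin", 40): (106.3, 86.0),
    ("rosuvastatin", 10): (98.2, 79.5),
    ("rosuvastatin", 20): (87.8, 72.6),
    ("rosuvastatin", 40): (79.0, 67.6),
    ("pravastatin", 10): (143.4, 108.6),
    ("pravastatin", 20): (136.2, 104.3),
    ("pravastatin", 40): (124.6, 96.9),
    ("pravastatin", 80): (115.9, 90.3),
}

#: bempedoic acid ED50 sampling distribution: estimate, SE, 95% CI
ED50_BA = (44.0, 3.8, (36.6, 51.3))
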