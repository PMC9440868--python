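"""Profile the drug-drug interaction coefficient on synthetic combination data.

With every single-drug parameter fixed at its published value, the marginal
likelihood is evaluated over a grid of candidate interaction coefficients;
the minimizer recovers the generating (less-than-additive) value.
"""

import numpy as np

from ldlresponse.datagen import Arm, TrialDesign, generate_trial
from ldlresponse.estimate import FitSpec, profile_gamma
from ldlresponse.params import bempedoic_model, population_params

design = TrialDesign(
    name="combo",
    arms=(
        Arm("atorvastatin", 20.0, 180.0, 250),
        Arm("atorvastatin", 40.0, 180.0, 250),
        Arm("simvastatin", 20.0, 180.0, 250),
        Arm("pravastatin", 40.0, 180.0, 250),
    ),
    population="atorvastatin",
)
dataset = generate_trial(design, seed=11)  # generated with gamma = -1.35

pop = population_params("atorvastatin")
ba = bempedoic_model("combination")
spec = FitSpec(
    free=(),
    fixed={
        "baseline": pop.baseline_typical, "emax": ba.emax, "ed50": ba.ed50,
        "hill": ba.hill, "omega_baseline": pop.omega_baseline,
        "omega_emax": pop.omega_emax, "prop": pop.residual_proportional,
        "add": pop.residual_additive,
    },
)
profile = profile_gamma(dataset, spec, np.arange(-3.0, 0.0001, 0.05))
obj = np.array(profile.objective)
print(f"grid minimizer: gamma = {profile.gamma_hat:+.2f} (generating value -1.35)")
print(f"objective drop vs additive (gamma=0): {obj[-1] - obj.min():.1f}")

# A clearly negative minimizer means the combination lowers LDL-C less than
# the sum of the single-drug effects -- consistent with both drugs acting on
# the same cholesterol-synthesis pathway.
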