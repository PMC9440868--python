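"""Published parameter fixtures and population-level parameter containers.

The packaged YAML fixture carries the fixed dose-response parameters for
bempedoic acid (monotherapy estimates with standard errors, and the values
fixed in the combination models), the four statin profiles (shared Emax and
Hill, per-statin ED50, baselines and variability), the common interaction
coefficient and the turnover loss rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import yaml

from .models import EmaxModel, InteractionModel, StatinProfile, TurnoverModel

__all__ = [
    "PopulationParams",
    "load_parameters",
    "bempedoic_model",
    "statin_profile",
    "statin_names",
    "interaction_model",
    "population_params",
    "monotherapy_population",
    "GAMMA",
    "KOUT_PER_H",
]

STATIN_NAMES = ("atorvastatin", "simvastatin", "rosuvastatin", "pravastatin")


@dataclass(frozen=True)
class PopulationParams:
    """Typical values plus variability magnitudes for a simulated population.

    ``omega_*`` are inter-individual coefficients of variation stored as
    fractions (a printed "27.1%" becomes 0.271); residual error combines a
    proportional fraction and an additive mg/dL component.
    """

    baseline_typical: float
    omega_baseline: float
    omega_emax: float
    residual_proportional: float
    residual_additive: float

    def __post_init__(self) -> None:
        for name in ("baseline_typical", "residual_proportional", "residual_additive"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.omega_baseline < 0 or self.omega_emax < 0:
            raise ValueError("omega values must be non-negative")

    @property
    def sigma_baseline(self) -> float:
        """Log-normal sigma matched to the baseline CV."""
        return cv_to_sigma(self.omega_baseline)

    @property
    def sigma_emax(self) -> float:
        """Log-normal sigma matched to the emax CV."""
        return cv_to_sigma(self.omega_emax)


def cv_to_sigma(cv: float) -> float:
    """Standard deviation of log X for a log-normal X with coefficient of variation ``cv``."""
    return math.sqrt(math.log1p(cv * cv))


@lru_cache(maxsize=1)
def load_parameters() -> dict:
    """Load the packaged parameter fixture as a nested dict."""
    text = resources.files("ldlresponse.data").joinpath("parameters.yaml").read_text()
    return yaml.safe_load(text)


def _params() -> dict:
    return load_parameters()


GAMMA: float = -1.35
KOUT_PER_H: float = 0.01


def bempedoic_model(context: str = "combination") -> EmaxModel:
    """Bempedoic acid Emax model.

    ``context`` selects the parameter set: ``"combination"`` uses the values
    fixed in the combination models (ED50 43.96 mg), ``"monotherapy"`` the
    monotherapy estimates (ED50 44.0 mg).  Both share emax 0.34 and hill 1.
    """
    p = _params()["bempedoic_acid"]
    if context == "combination":
        c = p["combination"]
        return EmaxModel(emax=c["emax"], ed50=c["ed50_mg"], hill=c["hill"])
    if context == "monotherapy":
        m = p["monotherapy"]
        return EmaxModel(
            emax=m["emax"]["estimate"],
            ed50=m["ed50_mg"]["estimate"],
            hill=m["hill"]["estimate"],
        )
    raise ValueError(f"unknown context {context!r}")


def statin_names() -> tuple[str, ...]:
    return STATIN_NAMES


def statin_profile(name: str) -> StatinProfile:
    """Dose-response profile for one of the four supported statins."""
    profiles = _params()["statin_profiles"]
    if name not in profiles:
        raise KeyError(f"unknown statin {name!r}; supported: {sorted(profiles)}")
    shared = _params()["statins"]["shared"]
    entry = profiles[name]
    model = EmaxModel(emax=shared["emax"], ed50=entry["ed50_mg"], hill=shared["hill"])
    return StatinProfile(
        name=name,
        model=model,
        max_label_dose=entry["max_label_dose_mg"],
        dose_grid=tuple(entry["dose_grid_mg"]),
    )


def interaction_model(statin: str | StatinProfile) -> InteractionModel:
    """Combination model of bempedoic acid with the given statin (gamma fixed)."""
    profile = statin if isinstance(statin, StatinProfile) else statin_profile(statin)
    return InteractionModel(
        drug_a=bempedoic_model("combination"),
        drug_b=profile.model,
        gamma=_params()["interaction"]["gamma"],
    )


def population_params(statin: str = "atorvastatin") -> PopulationParams:
    """Population parameters of a combination model (per-statin baseline and IIV).

    The goal-attainment simulations use the atorvastatin-model population for
    every statin, the highest-baseline condition in the source analysis.
    """
    entry = _params()["statin_profiles"][statin]
    mono = _params()["bempedoic_acid"]["monotherapy"]
    return PopulationParams(
        baseline_typical=entry["baseline_ldl_mgdl"]["estimate"],
        omega_baseline=entry["iiv_cv_baseline"]["estimate"],
        omega_emax=mono["iiv_cv"]["emax"]["estimate"],
        residual_proportional=entry["residual"]["proportional"]["estimate"],
        residual_additive=entry["residual"]["additive_mgdl"]["estimate"],
    )


def monotherapy_population() -> PopulationParams:
    """Population parameters of the bempedoic acid monotherapy model."""
    mono = _params()["bempedoic_acid"]["monotherapy"]
    return PopulationParams(
        baseline_typical=mono["baseline_ldl_mgdl"]["estimate"],
        omega_baseline=mono["iiv_cv"]["baseline"]["estimate"],
        omega_emax=mono["iiv_cv"]["emax"]["estimate"],
        residual_proportional=mono["residual"]["proportional"]["estimate"],
        residual_additive=mono["residual"]["additive_mgdl"]["estimate"],
    )


def turnover_model(baseline: float | None = None) -> TurnoverModel:
    """Turnover model with the fixed loss rate and a given (or typical) baseline."""
    if baseline is None:
        baseline = _params()["bempedoic_acid"]["monotherapy"]["baseline_ldl_mgdl"]["estimate"]
    return TurnoverModel(baseline=baseline, kout=_params()["turnover"]["kout_per_h"])
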