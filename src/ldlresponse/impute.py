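"""Back-calculation of pre-statin baseline LDL-C.

Patients enrolled on stable statin therapy contribute an on-statin entry
LDL-C; pooling them with treatment-naive patients requires the LDL-C they
would have off statins.  Deterministic mode inverts the statin
dose-response point effect:

    prestatin = observed / (1 - effect(dose))

Stochastic mode acknowledges that individual statin responses vary: the
fractional effect is perturbed by a log-normal population draw (default CV
30%, truncated so the drawn fraction stays below 0.95) before inversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import StatinProfile, fractional_effect
from .params import cv_to_sigma, statin_profile

__all__ = ["ImputationDraw", "impute_prestatin", "impute_dataset"]

#: drawn statin response fractions at or above this are rejected and redrawn
MAX_RESPONSE_FRACTION = 0.95

#: default CV of the population distribution of statin responses
DEFAULT_RESPONSE_CV = 0.30


@dataclass(frozen=True)
class ImputationDraw:
    """Audit record of one imputation: input, draw used and result."""

    observed_on_statin_baseline: float
    statin: str
    statin_dose: float
    response_draw: float
    imputed_prestatin_baseline: float

    def __post_init__(self) -> None:
        if self.response_draw > 0 and (
            self.imputed_prestatin_baseline < self.observed_on_statin_baseline
        ):
            raise ValueError("imputed baseline below observed despite positive response")


def _draw_response(point: float, cv: float, rng: np.random.Generator) -> float:
    sigma = cv_to_sigma(cv)
    for _ in range(1000):
        draw = point * np.exp(rng.normal(0.0, sigma))
        if draw < MAX_RESPONSE_FRACTION:
            return float(draw)
    raise RuntimeError("could not draw a statin response below the truncation bound")


def impute_prestatin(
    observed: float,
    statin: StatinProfile,
    dose: float,
    rng: np.random.Generator | None = None,
    response_cv: float = DEFAULT_RESPONSE_CV,
) -> ImputationDraw:
    """Impute the pre-statin baseline for one on-statin entry LDL-C.

    With ``rng`` None the inversion is deterministic at the point effect;
    otherwise the effect is drawn from the population response distribution
    first.  Dose 0 returns the observed value unchanged.
    """
    if observed <= 0:
        raise ValueError("observed LDL-C must be positive")
    if dose < 0:
        raise ValueError("dose must be non-negative")
    if dose == 0:
        return ImputationDraw(observed, statin.name, 0.0, 0.0, float(observed))
    point = fractional_effect(dose, statin.model)
    draw = point if rng is None else _draw_response(point, response_cv, rng)
    return ImputationDraw(
        observed_on_statin_baseline=float(observed),
        statin=statin.name,
        statin_dose=float(dose),
        response_draw=float(draw),
        imputed_prestatin_baseline=float(observed / (1.0 - draw)),
    )


def impute_dataset(
    dataset: pd.DataFrame,
    rng: np.random.Generator | None = None,
    response_cv: float = DEFAULT_RESPONSE_CV,
) -> pd.DataFrame:
    """Impute pre-statin baselines column-wise on a long-format trial dataset.

    Adds ``prestatin_baseline_mgdl`` and the audit column ``response_draw``
    to baseline-week records of subjects flagged on statin at entry; other
    records carry the observed value with a zero draw.
    """
    required = {"statin", "statin_dose_mg", "week", "ldl_mgdl", "on_statin_at_entry"}
    if not required.issubset(dataset.columns):
        raise KeyError(f"dataset missing columns: {sorted(required - set(dataset.columns))}")
    out = dataset.copy()
    out["prestatin_baseline_mgdl"] = out["ldl_mgdl"].astype(float)
    out["response_draw"] = 0.0
    mask = (out["week"] == 0) & out["on_statin_at_entry"].astype(bool) & (out["statin_dose_mg"] > 0)
    for idx in out.index[mask]:
        profile = statin_profile(str(out.at[idx, "statin"]))
        draw = impute_prestatin(
            out.at[idx, "ldl_mgdl"],
            profile,
            float(out.at[idx, "statin_dose_mg"]),
            rng=rng,
            response_cv=response_cv,
        )
        out.at[idx, "prestatin_baseline_mgdl"] = draw.imputed_prestatin_baseline
        out.at[idx, "response_draw"] = draw.response_draw
    return out
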