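"""Synthetic subject-level trial datasets.

The pooled clinical data behind the dose-response analysis are not public;
this module generates long-format datasets with the same statistical
structure: log-normal baselines, log-normal inter-individual variability on
the bempedoic acid maximal effect, combined proportional+additive residual
error, dose-ranging monotherapy arms and statin-background combination arms
whose entry baseline already reflects stable statin therapy.

Dataset columns (comma-separated text, header row, missing = empty field):

``subject_id, study, statin, statin_dose_mg, ba_dose_mg, week, ldl_mgdl,
on_statin_at_entry``
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .models import combined_effect, fractional_effect
from .params import (
    GAMMA,
    PopulationParams,
    bempedoic_model,
    monotherapy_population,
    population_params,
    statin_profile,
)
from .simulate import draw_subjects

__all__ = [
    "Arm",
    "TrialDesign",
    "generate_trial",
    "preset_designs",
    "write_dataset",
    "read_dataset",
]

DATASET_COLUMNS = [
    "subject_id",
    "study",
    "statin",
    "statin_dose_mg",
    "ba_dose_mg",
    "week",
    "ldl_mgdl",
    "on_statin_at_entry",
]


@dataclass(frozen=True)
class Arm:
    """One treatment arm: drug(s), doses and subjects enrolled."""

    statin: str | None
    statin_dose: float
    ba_dose: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("every arm needs n >= 1")
        if self.statin is None and self.statin_dose > 0:
            raise ValueError("statin dose without a statin")
        if self.statin_dose < 0 or self.ba_dose < 0:
            raise ValueError("doses must be non-negative")


@dataclass(frozen=True)
class TrialDesign:
    """Arms, visit schedule and population assignment of one synthetic trial."""

    name: str
    arms: tuple[Arm, ...]
    visit_weeks: tuple[int, ...] = (0, 12)
    population: str = "monotherapy"  # "monotherapy" or a statin name

    def __post_init__(self) -> None:
        if 0 not in self.visit_weeks or 12 not in self.visit_weeks:
            raise ValueError("visit schedule must include baseline (0) and week 12")
        if not self.arms:
            raise ValueError("design has no arms")


def _population(design: TrialDesign) -> PopulationParams:
    if design.population == "monotherapy":
        return monotherapy_population()
    return population_params(design.population)


def generate_trial(
    design: TrialDesign,
    seed,
    pop: PopulationParams | None = None,
    gamma: float = GAMMA,
    residual: bool = True,
    emax_iiv: bool = True,
) -> pd.DataFrame:
    """Generate a long-format dataset for one trial design.

    Observations are ``prediction * (1 + eps_prop) + eps_add`` (suppressed
    with ``residual=False``).  Combination-arm subjects are flagged on
    statin at entry and their week-0 record reflects the statin effect
    already applied, so the baseline-imputation stage sees realistic input.
    Fully reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    pop = pop if pop is not None else _population(design)
    ba = bempedoic_model("combination")
    records = []
    next_id = 1
    for arm in design.arms:
        shells = draw_subjects(arm.n, pop, rng, emax_iiv=emax_iiv, ba_model=ba)
        on_statin = arm.statin is not None and arm.statin_dose > 0
        e_statin = (
            fractional_effect(arm.statin_dose, statin_profile(arm.statin).model)
            if on_statin
            else 0.0
        )
        if arm.ba_dose > 0:
            dh = arm.ba_dose**ba.hill
            e_ba = shells["emax_ba"].to_numpy() * dh / (ba.ed50**ba.hill + dh)
            e_ba = np.clip(e_ba, 0.0, np.nextafter(1.0, 0.0))
        else:
            e_ba = np.zeros(arm.n)
        e_total = combined_effect(e_ba, np.full(arm.n, e_statin), gamma)
        baselines = shells["baseline"].to_numpy()
        for week in sorted(design.visit_weeks):
            if week == 0:
                # entry under stable background statin, before bempedoic acid
                pred = baselines * (1.0 - e_statin)
            else:
                pred = baselines * (1.0 - e_total)
            if residual:
                sd = np.sqrt(
                    (pop.residual_proportional * pred) ** 2 + pop.residual_additive**2
                )
                obs = pred + rng.normal(0.0, 1.0, size=arm.n) * sd
                obs = np.maximum(obs, 1.0)  # LDL-C stays positive
            else:
                obs = pred
            records.append(
                pd.DataFrame(
                    {
                        "subject_id": np.arange(next_id, next_id + arm.n),
                        "study": design.name,
                        "statin": arm.statin if on_statin else None,
                        "statin_dose_mg": arm.statin_dose if on_statin else 0.0,
                        "ba_dose_mg": float(arm.ba_dose),
                        "week": week,
                        "ldl_mgdl": obs,
                        "on_statin_at_entry": on_statin,
                    }
                )
            )
        next_id += arm.n
    out = pd.concat(records, ignore_index=True)
    out["statin"] = out["statin"].astype("string")
    return out.sort_values(["subject_id", "week"], ignore_index=True)


def preset_designs() -> dict[str, TrialDesign]:
    """Named trial designs used throughout the package.

    ``monotherapy_dose_ranging`` brackets the therapeutic 180 mg dose;
    ``rich_design`` adds a 20 mg arm below the half-maximal dose (44 mg) so
    ED50 is identifiable in recovery studies; ``combination_per_statin``
    covers each statin's supported grid with and without bempedoic acid 180
    mg; ``pooled_phase3_like`` mimics an add-on-to-statin phase 3 layout.
    No simvastatin or rosuvastatin 80 mg arm exists anywhere.
    """
    mono = TrialDesign(
        name="monotherapy_dose_ranging",
        arms=tuple(Arm(None, 0.0, d, 200) for d in (0, 60, 120, 180, 240)),
    )
    rich = replace(
        mono,
        name="rich_design",
        arms=tuple(Arm(None, 0.0, d, 167) for d in (0, 20, 60, 120, 180, 240)),
    )
    combo_arms = []
    for name in ("atorvastatin", "simvastatin", "rosuvastatin", "pravastatin"):
        for dose in statin_profile(name).dose_grid:
            combo_arms.append(Arm(name, float(dose), 0.0, 50))
            combo_arms.append(Arm(name, float(dose), 180.0, 50))
    combo = TrialDesign(
        name="combination_per_statin",
        arms=tuple(combo_arms),
        population="atorvastatin",
    )
    phase3 = TrialDesign(
        name="pooled_phase3_like",
        arms=(
            Arm("atorvastatin", 40.0, 0.0, 250),
            Arm("atorvastatin", 40.0, 180.0, 500),
            Arm("simvastatin", 20.0, 0.0, 125),
            Arm("simvastatin", 20.0, 180.0, 250),
        ),
        population="atorvastatin",
    )
    return {d.name: d for d in (mono, rich, combo, phase3)}


def write_dataset(dataset: pd.DataFrame, path) -> None:
    """Write a long-format dataset as comma-separated text (lossless floats)."""
    dataset.to_csv(path, index=False, float_format="%.17g")


def read_dataset(path) -> pd.DataFrame:
    """Read a dataset written by :func:`write_dataset`."""
    out = pd.read_csv(path, dtype={"statin": "string"}, float_precision="round_trip")
    missing = [c for c in DATASET_COLUMNS if c not in out.columns]
    if missing:
        raise ValueError(f"not a trial dataset; missing columns {missing}")
    return out
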