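"""Report surfaces: percent-change and absolute-LDL tables, goal attainment.

The stochastic tables follow the published simulation procedure: one
patient per parameter-replicate set, 1000 parameter sets per dosing
condition, with the baseline LDL-C population (typical value and
inter-individual variability) of the atorvastatin combination model shared
by every statin.  Parameter uncertainty enters through a parametric
bootstrap of the bempedoic acid monotherapy estimates (emax, ED50); all
statin and interaction parameters are fixed without error, so their
contribution to the spread is nil by construction.

Deterministic mode disables variability and bootstrap entirely and reduces
every cell to the closed-form typical-value prediction.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import numpy as np
import pandas as pd

from . import __version__
from .models import EmaxModel, combined_effect, delta_added_effect, fractional_effect, percent_change
from .params import (
    GAMMA,
    bempedoic_model,
    load_parameters,
    population_params,
    statin_names,
    statin_profile,
)
from .simulate import DEFAULT_THRESHOLDS

__all__ = [
    "table3",
    "table4",
    "attainment",
    "write_report",
    "provenance",
]

BA_REPORT_DOSE = 180.0


def provenance(seed=None) -> dict[str, str]:
    """Provenance metadata attached to every emitted artifact."""
    raw = resources.files("ldlresponse.data").joinpath("parameters.yaml").read_bytes()
    return {
        "package_version": __version__,
        "fixture_sha256": hashlib.sha256(raw).hexdigest()[:16],
        "seed": "none" if seed is None else str(seed),
    }


def _antithetic_normal(rng: np.random.Generator, n: int) -> np.ndarray:
    """Standard-normal draws in antithetic pairs (z, -z) for variance reduction."""
    half = rng.normal(0.0, 1.0, size=(n + 1) // 2)
    return np.concatenate([half, -half])[:n]


def _ba_replicates(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Parametric-bootstrap replicates of the bempedoic acid emax and ED50."""
    mono = load_parameters()["bempedoic_acid"]["monotherapy"]
    emax = mono["emax"]["estimate"] + mono["emax"]["se"] * _antithetic_normal(rng, n)
    ed50 = mono["ed50_mg"]["estimate"] + mono["ed50_mg"]["se"] * _antithetic_normal(rng, n)
    return np.clip(emax, 1e-6, 0.999), np.maximum(ed50, 1e-3)


class _CommonPopulation:
    """Shared patient population for all cells of one simulated table.

    One baseline and one bempedoic parameter replicate per patient, drawn
    once and reused across dosing conditions so that between-cell contrasts
    are not diluted by Monte-Carlo noise.
    """

    def __init__(self, n: int, seed, param_uncertainty: bool = True):
        rng = np.random.default_rng(seed)
        pop = population_params("atorvastatin")
        self.pop = pop
        self.baselines = pop.baseline_typical * np.exp(
            pop.sigma_baseline * _antithetic_normal(rng, n)
        )
        if param_uncertainty:
            self.emax_ba, self.ed50_ba = _ba_replicates(n, rng)
        else:
            ba = bempedoic_model("combination")
            self.emax_ba = np.full(n, ba.emax)
            self.ed50_ba = np.full(n, ba.ed50)
        self.hill_ba = bempedoic_model("combination").hill

    def effects(self, statin_model: EmaxModel | None, statin_dose: float, ba_dose: float):
        n = len(self.baselines)
        if ba_dose > 0:
            dh = ba_dose**self.hill_ba
            e_ba = self.emax_ba * dh / (self.ed50_ba**self.hill_ba + dh)
        else:
            e_ba = np.zeros(n)
        e_st = fractional_effect(statin_dose, statin_model) if statin_dose > 0 else 0.0
        return combined_effect(e_ba, np.full(n, float(e_st)), GAMMA)

    def ldl(self, e_total: np.ndarray) -> np.ndarray:
        return self.baselines * (1.0 - e_total)


def _point_effect(statin: str | None, statin_dose: float, ba_dose: float) -> float:
    ba = bempedoic_model("combination")
    e_ba = fractional_effect(ba_dose, ba) if ba_dose > 0 else 0.0
    e_st = (
        fractional_effect(statin_dose, statin_profile(statin).model)
        if statin is not None and statin_dose > 0
        else 0.0
    )
    return combined_effect(e_ba, e_st, GAMMA)


def table3(
    n: int = 1000,
    seed=0,
    deterministic: bool = False,
    ba_dose: float = BA_REPORT_DOSE,
) -> pd.DataFrame:
    """Statin-by-dose grid of mean (90% interval) percent change, with the
    additional lowering attributable to bempedoic acid (``delta_pct``).

    One row per statin and dose (dose 0 carries the bempedoic acid
    monotherapy column).  Deterministic mode collapses every interval onto
    the closed-form point prediction.
    """
    common = None if deterministic else _CommonPopulation(n, seed)
    rows = []
    for name in statin_names():
        profile = statin_profile(name)
        for dose in (0.0, *profile.dose_grid):
            row = {"statin": name, "statin_dose": float(dose)}
            for label, ba in (("alone", 0.0), ("combo", ba_dose)):
                if dose == 0 and ba == 0:
                    row.update({f"{label}_pct": np.nan, f"{label}_lo": np.nan, f"{label}_hi": np.nan})
                    continue
                if deterministic:
                    pct = percent_change(_point_effect(name, dose, ba))
                    lo = hi = pct
                else:
                    pct_i = percent_change(common.effects(profile.model, dose, ba))
                    pct = float(np.mean(pct_i))
                    lo, hi = np.percentile(pct_i, [5.0, 95.0])
                row.update({f"{label}_pct": pct, f"{label}_lo": float(lo), f"{label}_hi": float(hi)})
            if dose > 0:
                row["delta_pct"] = delta_added_effect(row["combo_pct"], row["alone_pct"])
            else:
                row["delta_pct"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def table4(
    n: int = 1000,
    seed=0,
    deterministic: bool = False,
    ba_dose: float = BA_REPORT_DOSE,
) -> pd.DataFrame:
    """Statin-by-dose grid of mean absolute week-12 LDL-C (mg/dL).

    All statins share the atorvastatin-model baseline population; the dose-0
    row holds the untreated mean baseline and the bempedoic acid monotherapy
    mean.
    """
    common = None if deterministic else _CommonPopulation(n, seed)
    rows = []
    for name in statin_names():
        profile = statin_profile(name)
        base = population_params("atorvastatin").baseline_typical
        for dose in (0.0, *profile.dose_grid):
            row = {"statin": name, "statin_dose": float(dose)}
            for label, ba in (("alone", 0.0), ("combo", ba_dose)):
                if deterministic:
                    row[f"{label}_ldl"] = base * (1.0 - _point_effect(name, dose, ba))
                else:
                    e = common.effects(profile.model, dose, ba)
                    row[f"{label}_ldl"] = float(np.mean(common.ldl(e)))
            rows.append(row)
    return pd.DataFrame(rows)


def attainment(
    n: int = 1000,
    seed=0,
    thresholds=DEFAULT_THRESHOLDS,
    ba_dose: float = BA_REPORT_DOSE,
) -> pd.DataFrame:
    """Proportion of simulated patients below each LDL-C goal.

    One row per statin, dose and bempedoic acid arm (0 or ``ba_dose`` mg),
    with one ``p_below_<threshold>`` column per goal.
    """
    common = _CommonPopulation(n, seed)
    rows = []
    for name in statin_names():
        profile = statin_profile(name)
        for dose in (0.0, *profile.dose_grid):
            for ba in (0.0, ba_dose):
                e = common.effects(profile.model, dose, ba)
                ldl = common.ldl(e)
                row = {"statin": name, "statin_dose": float(dose), "ba_dose": float(ba)}
                for thr in thresholds:
                    row[f"p_below_{int(thr)}"] = float(np.mean(ldl < thr))
                rows.append(row)
    return pd.DataFrame(rows)


def write_report(df: pd.DataFrame, path, seed=None) -> None:
    """Write a report table as delimited text with provenance header lines."""
    meta = provenance(seed)
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False, float_format="%.6g")
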