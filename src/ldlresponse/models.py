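"""Deterministic dose-response algebra for LDL-C lowering.

The endpoint model is an indirect-effect (turnover) model in which drug
effect inhibits LDL-C production: dL/dt = kin*(1 - E) - kout*L with
kin = baseline * kout, so the steady state under total fractional effect
``E`` is ``baseline * (1 - E)``.  Dose maps to effect through a (sigmoid)
Emax relationship per drug, and two drugs combine through a single
interaction coefficient gamma.

Sign convention: effects are stored and returned as *positive fractions of
baseline lowered* (0.27 means a 27% reduction).  Published parameter tables
report them as negative proportional changes; :func:`percent_change`
converts back to that reporting scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EmaxModel",
    "StatinProfile",
    "InteractionModel",
    "TurnoverModel",
    "fractional_effect",
    "combined_effect",
    "ldl_timecourse",
    "percent_change",
    "delta_added_effect",
    "mgdl_to_mmoll",
]

#: mg/dL per mmol/L for LDL cholesterol
MGDL_PER_MMOLL = 38.67


@dataclass(frozen=True)
class EmaxModel:
    """Saturating dose-response for one drug.

    Parameters
    ----------
    emax
        Maximal fractional lowering of baseline LDL-C, in (0, 1).
    ed50
        Dose (mg) producing half-maximal effect.
    hill
        Hill coefficient; 1 gives the simple Emax model.
    """

    emax: float
    ed50: float
    hill: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.emax < 1.0:
            raise ValueError(f"emax must be in (0, 1), got {self.emax}")
        if self.ed50 <= 0.0:
            raise ValueError(f"ed50 must be positive, got {self.ed50}")
        if self.hill <= 0.0:
            raise ValueError(f"hill must be positive, got {self.hill}")

    def effect(self, dose):
        """Fractional effect at ``dose`` mg; alias of :func:`fractional_effect`."""
        return fractional_effect(dose, self)


@dataclass(frozen=True)
class StatinProfile:
    """A named statin with its dose-response model and supported dose grid."""

    name: str
    model: EmaxModel
    max_label_dose: float
    dose_grid: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.dose_grid):
            raise ValueError("dose_grid entries must be positive")
        if tuple(sorted(self.dose_grid)) != tuple(self.dose_grid):
            raise ValueError("dose_grid must be ordered")


@dataclass(frozen=True)
class InteractionModel:
    """Two single-drug models joined by an interaction coefficient.

    With ``gamma < 0`` the combined lowering is less than additive; the
    fixed published value is -1.35 for every statin with bempedoic acid.
    """

    drug_a: EmaxModel
    drug_b: EmaxModel
    gamma: float

    def total_effect(self, dose_a, dose_b):
        """Total fractional effect of ``dose_a`` of drug A with ``dose_b`` of B."""
        e_a = fractional_effect(dose_a, self.drug_a)
        e_b = fractional_effect(dose_b, self.drug_b)
        return combined_effect(e_a, e_b, self.gamma)


@dataclass(frozen=True)
class TurnoverModel:
    """Indirect-effect turnover model for LDL-C.

    ``kin`` is derived as ``baseline * kout`` so that the steady state at
    zero effect equals the baseline.
    """

    baseline: float
    kout: float = 0.01
    kin: float = field(init=False)

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError(f"baseline must be positive, got {self.baseline}")
        if self.kout <= 0:
            raise ValueError(f"kout must be positive, got {self.kout}")
        object.__setattr__(self, "kin", self.baseline * self.kout)


def fractional_effect(dose, model: EmaxModel):
    """Fractional LDL-C lowering at ``dose`` mg under an Emax model.

    Implements ``emax * dose**hill / (ed50**hill + dose**hill)``: zero at
    dose 0, strictly increasing, bounded above by ``emax``.  Accepts scalars
    or arrays; negative doses raise ``ValueError``.
    """
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be non-negative")
    dh = np.where(dose > 0, dose, 1.0) ** model.hill  # guard 0**h underflow paths
    eff = np.where(dose > 0, model.emax * dh / (model.ed50**model.hill + dh), 0.0)
    return float(eff) if eff.ndim == 0 else eff


def combined_effect(e_a, e_b, gamma: float):
    """Total fractional effect of two drugs with interaction ``gamma``.

    ``e_total = e_a + e_b + gamma * e_a * e_b`` on the positive-fraction
    scale, clamped to [0, 1).  Reduces to ``e_a`` when ``e_b`` is 0 and
    vice versa.  A pathological gamma driving the total negative is clamped
    to 0 with a warning.
    """
    e_a = np.asarray(e_a, dtype=float)
    e_b = np.asarray(e_b, dtype=float)
    if np.any((e_a < 0) | (e_a >= 1)) or np.any((e_b < 0) | (e_b >= 1)):
        raise ValueError("single-drug effects must lie in [0, 1)")
    if not np.isfinite(gamma):
        raise ValueError("gamma must be finite")
    total = e_a + e_b + gamma * e_a * e_b
    if np.any(total < 0):
        warnings.warn(
            "combined effect below zero (pathological gamma); clamping to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    total = np.clip(total, 0.0, np.nextafter(1.0, 0.0))
    return float(total) if total.ndim == 0 else total


def ldl_timecourse(turnover: TurnoverModel, e_total, t):
    """LDL-C (mg/dL) at time ``t`` hours after onset of a constant effect.

    Closed-form solution of the linear turnover ODE with production
    inhibited by ``e_total``:
    ``baseline * (1 - e_total * (1 - exp(-kout * t)))``.  Returns the
    baseline at t = 0 and approaches ``baseline * (1 - e_total)``
    monotonically.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    e_total = np.asarray(e_total, dtype=float)
    ldl = turnover.baseline * (1.0 - e_total * (1.0 - np.exp(-turnover.kout * t)))
    return float(ldl) if ldl.ndim == 0 else ldl


def percent_change(e_total):
    """Signed percent change from baseline for a fractional effect (-100*e)."""
    e_total = np.asarray(e_total, dtype=float)
    if np.any((e_total < 0) | (e_total >= 1)):
        raise ValueError("e_total must lie in [0, 1)")
    out = -100.0 * e_total
    return float(out) if out.ndim == 0 else out


def delta_added_effect(combo_pct, mono_pct):
    """Additional percent lowering attributable to the added drug.

    Re-expresses the combination effect on the on-statin baseline scale:
    ``(combo - mono) / (1 + mono / 100)`` with both arguments as signed
    percent changes.  ``mono_pct`` of -100 (total lowering) is undefined.
    """
    combo_pct = np.asarray(combo_pct, dtype=float)
    mono_pct = np.asarray(mono_pct, dtype=float)
    if np.any(mono_pct <= -100):
        raise ZeroDivisionError("monotherapy change of -100% leaves no baseline")
    out = (combo_pct - mono_pct) / (1.0 + mono_pct / 100.0)
    return float(out) if out.ndim == 0 else out


def mgdl_to_mmoll(value):
    """Convert LDL-C from mg/dL to mmol/L (divide by 38.67)."""
    value = np.asarray(value, dtype=float)
    if np.any(value < 0):
        raise ValueError("LDL-C cannot be negative")
    out = value / MGDL_PER_MMOLL
    return float(out) if out.ndim == 0 else out
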