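"""Intravenous bolus dosing as instantaneous state jumps.

Infusion duration is negligible on the model's timescale, so each dose of
``xi`` mg raises the free-drug concentration by ``xi * f_pembro`` molec/cm^3
in *both* compartments simultaneously (the same linear dose-to-concentration
scaling applies at the tumour site and in the draining lymph node). Impulses
never pass through the adaptive integrator: the driver stops exactly at each
dose time, applies the jump, and restarts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fullmodel import FULL_INDEX, FULL_VARS
from .params import ModelParams
from .reduced import REDUCED_INDEX, REDUCED_VARS

__all__ = ["DoseEvent", "apply_impulse"]


@dataclass(frozen=True)
class DoseEvent:
    """One infusion: time in days, dose in mg."""

    time: float
    dose_mg: float

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("dose time must be >= 0")
        if self.dose_mg < 0:
            raise ValueError("dose must be >= 0")


def apply_impulse(y: np.ndarray, xi: float, p: ModelParams) -> np.ndarray:
    """Return a copy of the state with one bolus of ``xi`` mg applied.

    Accepts a full (32) or reduced (20) state vector; only the two drug
    components change, each by exactly ``xi * f_pembro``.
    """
    if xi < 0:
        raise ValueError("dose must be >= 0")
    y = np.array(y, dtype=float, copy=True)
    if len(y) == len(FULL_VARS):
        index = FULL_INDEX
    elif len(y) == len(REDUCED_VARS):
        index = REDUCED_INDEX
    else:
        raise ValueError(f"state of length {len(y)} is neither full nor reduced")
    jump = xi * p.f_pembro
    y[index["A_1"]] += jump
    y[index["A1_LN"]] += jump
    return y
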