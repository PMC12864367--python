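"""Deterministic integration driver, trajectory containers and comparisons.

Integration is piecewise between infusion times: the solver is stopped
exactly at each dose time, the bolus jump is applied, and integration
restarts, so impulses never pass through the adaptive stepper. The solver is
an adaptive low-order explicit Runge-Kutta pair (scipy's RK23); the save
grid is decoupled from solver steps via dense output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import fullmodel, reduced
from .dosing import apply_impulse
from .fullmodel import FULL_INDEX, FULL_VARS, OUTPUT_VARS, algebraic_complexes
from .params import DoseSchedule, InitialState, ModelParams
from .reduced import REDUCED_INDEX, REDUCED_VARS, embed_reduced

__all__ = ["Trajectory", "integrate", "compare_trajectories", "TRAJ_COLUMNS"]

#: Trajectory column order: every reported variable plus total cancer V.
TRAJ_COLUMNS: tuple[str, ...] = OUTPUT_VARS + ("V",)


@dataclass
class Trajectory:
    """Time-indexed state record in dimensional units.

    ``kind`` tags provenance (``full``, ``reduced`` or ``abm-replicate-k``);
    ``manifest`` records run configuration, seeds and group sizes.
    """

    times: np.ndarray
    data: np.ndarray
    columns: tuple[str, ...] = TRAJ_COLUMNS
    kind: str = "full"
    manifest: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("save times must be strictly increasing")
        if self.data.shape != (len(self.times), len(self.columns)):
            raise ValueError("data shape does not match times/columns")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[:, self.columns.index(name)]

    def final(self, name: str) -> float:
        return float(self[name][-1])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, columns=list(self.columns))
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")
        manifest = dict(self.manifest, kind=self.kind)
        Path(path).with_suffix(".manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str)
        )

    @classmethod
    def from_csv(cls, path: str | Path, kind: str = "loaded") -> "Trajectory":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(
            times=df["time"].to_numpy(),
            data=df.drop(columns="time").to_numpy(),
            columns=tuple(c for c in df.columns if c != "time"),
            kind=kind,
        )


def _expand_full(y: np.ndarray, p: ModelParams) -> np.ndarray:
    """Full state -> output row (adds algebraic complexes and V)."""
    cx = algebraic_complexes(y, p)
    v = fullmodel.total_cancer(y)
    return np.concatenate([y, [cx.Q_T8, cx.Q_K, cx.Q_8LN, v]])


def _expand_reduced(y: np.ndarray, p: ModelParams) -> np.ndarray:
    full = embed_reduced(y, p)
    return _expand_full(full, p)


def integrate(
    model: Literal["full", "reduced"],
    init: InitialState,
    params: ModelParams,
    schedule: DoseSchedule | None = None,
    t_final: float = 126.0,
    save_grid: Sequence[float] | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    method: str = "RK23",
) -> Trajectory:
    """Integrate the full or reduced model with bolus dosing.

    Saved values at a dose time are post-jump. The manifest records, for each
    applied dose, the free-drug concentration immediately before and after
    the jump.
    """
    if t_final <= 0:
        raise ValueError("t_final must be > 0")
    schedule = schedule or DoseSchedule.empty()
    if model == "full":
        y0 = fullmodel.full_initial_vector(init)
        rhs, expand = fullmodel.rhs_full, _expand_full
        a1_index = FULL_INDEX["A_1"]
    elif model == "reduced":
        y0 = reduced.reduced_initials(init, params)
        rhs, expand = reduced.rhs_reduced, _expand_reduced
        a1_index = REDUCED_INDEX["A_1"]
    else:
        raise ValueError(f"unknown model {model!r}")

    if save_grid is None:
        save_grid = np.linspace(0.0, t_final, int(round(t_final * 4)) + 1)
    save_grid = np.asarray(save_grid, dtype=float)
    if save_grid[0] < 0 or save_grid[-1] > t_final:
        raise ValueError("save grid must lie within [0, t_final]")

    def clipped_rhs(t, y):
        return rhs(t, np.maximum(y, 0.0), params)

    dose_events = [(t, xi) for t, xi in schedule.events if t <= t_final]
    breakpoints = sorted({0.0, t_final, *(t for t, _ in dose_events)})
    doses_at = {}
    for t, xi in dose_events:
        doses_at[t] = doses_at.get(t, 0.0) + xi

    saved = np.empty((len(save_grid), len(TRAJ_COLUMNS)))
    filled = np.zeros(len(save_grid), dtype=bool)
    jumps: list[dict] = []
    y = y0.copy()
    for seg_start, seg_end in zip(breakpoints[:-1], breakpoints[1:]):
        if seg_start in doses_at:
            pre = float(y[a1_index])
            y = apply_impulse(y, doses_at[seg_start], params)
            jumps.append({
                "time": seg_start, "dose_mg": doses_at[seg_start],
                "A_1_pre": pre, "A_1_post": float(y[a1_index]),
            })
        mask = (save_grid >= seg_start) & (save_grid < seg_end) & ~filled
        sol = solve_ivp(
            clipped_rhs, (seg_start, seg_end), y, method=method,
            rtol=rtol, atol=atol, dense_output=True,
        )
        if not sol.success:
            raise RuntimeError(
                f"integration failed in [{seg_start}, {seg_end}]: {sol.message}"
            )
        if mask.any():
            states = sol.sol(save_grid[mask])
            for k, idx in enumerate(np.where(mask)[0]):
                saved[idx] = expand(np.maximum(states[:, k], 0.0), params)
            filled[mask] = True
        y = np.maximum(sol.y[:, -1], 0.0)
    if t_final in doses_at:  # terminal dose: applied, not integrated past
        pre = float(y[a1_index])
        y = apply_impulse(y, doses_at[t_final], params)
        jumps.append({
            "time": t_final, "dose_mg": doses_at[t_final],
            "A_1_pre": pre, "A_1_post": float(y[a1_index]),
        })
        if save_grid[-1] == t_final:
            filled[-1] = False
    if not filled[-1] and save_grid[-1] == t_final:
        saved[-1] = expand(y, params)
        filled[-1] = True
    if not filled.all():
        raise RuntimeError("internal error: unsaved grid points")

    manifest = {
        "model": model,
        "rtol": rtol, "atol": atol, "method": method,
        "t_final": t_final,
        "schedule": list(schedule.events),
        "dose_jumps": jumps,
        "params": params.to_dict(),
    }
    return Trajectory(
        times=save_grid, data=saved, kind=model, manifest=manifest
    )


def compare_trajectories(
    a: Trajectory,
    b: Trajectory,
    variables: Sequence[str] | None = None,
    norm: Literal["sup", "l2"] = "sup",
    floor: float = 1e-9,
    t_min: float | None = None,
) -> dict[str, float]:
    """Per-variable relative discrepancy between two trajectories.

    ``b`` is resampled onto ``a``'s grid by linear interpolation over the
    overlapping time range; ``floor`` (relative to each variable's sup
    magnitude) guards the denominator near zero; ``t_min`` discards an
    initial transient.
    """
    lo = max(a.times[0], b.times[0])
    hi = min(a.times[-1], b.times[-1])
    if lo >= hi:
        raise ValueError("trajectories have disjoint time ranges")
    if t_min is not None:
        lo = max(lo, t_min)
        if lo >= hi:
            raise ValueError("t_min leaves no overlapping times")
    sel = (a.times >= lo) & (a.times <= hi)
    times = a.times[sel]
    variables = tuple(variables) if variables is not None else tuple(
        v for v in a.columns if v in b.columns
    )
    scores: dict[str, float] = {}
    for name in variables:
        ref = a[name][sel]
        other = np.interp(times, b.times, b[name])
        scale = max(np.max(np.abs(ref)), 0.0)
        denom = np.maximum(np.abs(ref), floor * scale if scale > 0 else 1.0)
        rel = np.abs(ref - other) / denom
        scores[name] = float(np.max(rel) if norm == "sup"
                             else np.sqrt(np.mean(rel**2)))
    return scores
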