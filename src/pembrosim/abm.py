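"""Stochastic agent-based analogue of the reduced model.

Time-driven synchronous scheme on a uniform grid of spacing ``dt``: at each
step, every continuous-time hazard lambda is mapped to a per-step occurrence
probability 1 - exp(-lambda * dt). Competing events acting on one agent are
combined into a single removal probability from the *total* hazard, with the
realised cause drawn categorically proportional to the individual hazards —
this avoids removing one agent twice in a step and agrees with the per-event
Bernoulli scheme to first order in dt. Because agents of one species are
exchangeable, per-agent trials are aggregated into binomial and multinomial
draws over the species count. Fractional spawn counts are realised by
floor-plus-Bernoulli so every spawn has exactly its target expectation. All
changes are computed from the frozen start-of-step state and committed
simultaneously; in the mean-field limit the scheme is the stochastic
analogue of first-order forward Euler for the reduced system.

Counts are whole-compartment agent totals: one agent of species X represents
a concentration gamma_X = g_X / V_compartment, so with the standard group
sizes the run starts from 5000 viable-cancer agents, 2000 agents of most
cell species and 1000 of each checkpoint pool. Free drug and checkpoint
pools are agent counts under the same rules; saturation factors are
evaluated on the re-dimensionalised totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .params import DoseSchedule, InitialState, ModelParams
from .reduced import (
    REDUCED_INDEX,
    REDUCED_VARS,
    fast_observables,
    reduced_processes,
)
from .scaling import ScalingSet, make_scalings
from .simulate import TRAJ_COLUMNS, Trajectory, _expand_reduced

__all__ = [
    "event_probability",
    "integer_spawn",
    "AgentEnsemble",
    "abm_step",
    "expected_step_increment",
    "run_abm",
]


def event_probability(lam: float, dt: float) -> float:
    """Per-step occurrence probability 1 - exp(-lam*dt) of a rate-lam event."""
    if lam < 0:
        raise ValueError("rate must be >= 0")
    if dt <= 0:
        raise ValueError("time step must be > 0")
    return -math.expm1(-lam * dt)


def integer_spawn(mean: float, rng: np.random.Generator) -> int:
    """Integer draw floor(mean) + Bernoulli(frac(mean)); expectation = mean."""
    if mean < 0:
        raise ValueError("spawn mean must be >= 0")
    base = math.floor(mean)
    frac = mean - base
    return base + (1 if (frac > 0 and rng.random() < frac) else 0)


@dataclass
class AgentEnsemble:
    """Integer agent counts for the 20 slow species plus the conversion to
    dimensional concentrations (gamma = concentration per agent)."""

    counts: np.ndarray          # int64, REDUCED_VARS order
    gamma: np.ndarray           # float, concentration per agent
    t: float = 0.0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.counts.shape != (len(REDUCED_VARS),):
            raise ValueError("counts must cover the 20 slow species")
        if np.any(self.counts < 0):
            raise ValueError("agent counts must be >= 0")
        if np.any(self.gamma <= 0):
            raise ValueError("per-agent sizes must be > 0")

    @classmethod
    def from_initial(
        cls, init: InitialState, p: ModelParams, scalings: ScalingSet
    ) -> "AgentEnsemble":
        gamma = scalings.per_agent(p).reduced_vector()
        y0 = np.array([init[name] for name in REDUCED_VARS])
        return cls(counts=np.rint(y0 / gamma).astype(np.int64), gamma=gamma)

    def dimensional(self) -> np.ndarray:
        """Re-dimensionalised slow state X = gamma_X * count."""
        return self.gamma * self.counts

    def fast(self, p: ModelParams):
        """Fast observables, always consistent with the current counts."""
        return fast_observables(self.dimensional(), p)


def abm_step(
    ens: AgentEnsemble, p: ModelParams, dt: float, rng: np.random.Generator
) -> AgentEnsemble:
    """One synchronous update; returns a new ensemble at t + dt."""
    if dt <= 0:
        raise ValueError("time step must be > 0")
    y = ens.dimensional()
    proc = reduced_processes(y, p)
    counts = ens.counts
    gamma = ens.gamma
    delta = np.zeros(len(REDUCED_VARS), dtype=np.int64)

    # group outgoing transitions by source species
    trans_by_src: dict[str, list[tuple[str, float, float]]] = {}
    for src, dest, hazard, factor in proc.transitions:
        trans_by_src.setdefault(src, []).append((dest, hazard, factor))

    # zeroth-order sources
    for name, flux in proc.sources.items():
        i = REDUCED_INDEX[name]
        delta[i] += integer_spawn(flux / gamma[i] * dt, rng)

    for i, name in enumerate(REDUCED_VARS):
        n = int(counts[i])
        if n == 0:
            continue
        # births leave the parent in place and add offspring
        b = proc.births.get(name, 0.0)
        if b > 0.0:
            delta[i] += rng.binomial(n, -math.expm1(-b * dt))
        # competing removals: one total-hazard trial per agent, cause drawn
        # categorically; aggregated to binomial + multinomial over the count
        hazards = list(proc.losses.get(name, ()))
        trans = trans_by_src.get(name, ())
        hazards.extend(h for _, h, _ in trans)
        h_tot = sum(hazards)
        if h_tot <= 0.0:
            continue
        n_events = rng.binomial(n, -math.expm1(-h_tot * dt))
        if n_events == 0:
            continue
        delta[i] -= n_events
        if trans:
            probs = np.array(hazards) / h_tot
            split = rng.multinomial(n_events, probs)
            n_losses = len(proc.losses.get(name, ()))
            for k, (dest, _h, factor) in enumerate(trans):
                n_tr = int(split[n_losses + k])
                if n_tr:
                    j = REDUCED_INDEX[dest]
                    mult = factor * gamma[i] / gamma[j]
                    delta[j] += integer_spawn(n_tr * mult, rng)

    new_counts = counts + delta
    if np.any(new_counts < 0):  # removals are bounded by counts; unreachable
        raise RuntimeError("agent count went negative")
    return replace(ens, counts=new_counts, t=ens.t + dt)


def expected_step_increment(
    ens: AgentEnsemble, p: ModelParams, dt: float
) -> np.ndarray:
    """Exact expectation of the one-step count increment.

    Every draw in :func:`abm_step` has a closed-form mean (binomial,
    multinomial, floor-plus-Bernoulli), so the expectation is available
    without sampling; it matches the reduced-ODE forward-Euler increment to
    O(dt^2)."""
    y = ens.dimensional()
    proc = reduced_processes(y, p)
    gamma = ens.gamma
    exp_delta = np.zeros(len(REDUCED_VARS))
    for name, flux in proc.sources.items():
        i = REDUCED_INDEX[name]
        exp_delta[i] += flux / gamma[i] * dt
    trans_by_src: dict[str, list[tuple[str, float, float]]] = {}
    for src, dest, hazard, factor in proc.transitions:
        trans_by_src.setdefault(src, []).append((dest, hazard, factor))
    for i, name in enumerate(REDUCED_VARS):
        n = int(ens.counts[i])
        if n == 0:
            continue
        b = proc.births.get(name, 0.0)
        if b > 0.0:
            exp_delta[i] += n * -math.expm1(-b * dt)
        hazards = list(proc.losses.get(name, ()))
        trans = trans_by_src.get(name, ())
        hazards.extend(h for _, h, _ in trans)
        h_tot = sum(hazards)
        if h_tot <= 0.0:
            continue
        p_event = -math.expm1(-h_tot * dt)
        exp_delta[i] -= n * p_event
        for dest, h, factor in trans:
            j = REDUCED_INDEX[dest]
            exp_delta[j] += n * p_event * (h / h_tot) * factor * gamma[i] / gamma[j]
    return exp_delta


def run_abm(
    init: InitialState,
    params: ModelParams,
    schedule: DoseSchedule | None = None,
    t_final: float = 126.0,
    dt: float = 0.01,
    n_reps: int = 10,
    seed: int = 0,
    save_dt: float = 0.5,
    scalings: ScalingSet | None = None,
) -> list[Trajectory]:
    """Run independent ABM replicates and return dimensional trajectories.

    Replicate streams are spawned deterministically from the root seed via
    ``numpy.random.SeedSequence(seed).spawn``; identical arguments give
    bit-identical output. Dose times are snapped to the nearest grid point
    (maximum error dt/2) and a dose at t = 0 is applied before the first
    step; saved rows record the state at the start of each save step,
    re-dimensionalised and expanded with the fast observables.
    """
    if t_final <= 0:
        raise ValueError("t_final must be > 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    schedule = schedule or DoseSchedule.empty()
    scalings = scalings or make_scalings(init, params)
    gamma = scalings.per_agent(params).reduced_vector()

    n_steps = int(round(t_final / dt))
    save_every = max(1, int(round(save_dt / dt)))
    save_steps = np.arange(0, n_steps + 1, save_every)
    if save_steps[-1] != n_steps:
        save_steps = np.append(save_steps, n_steps)
    save_set = set(int(s) for s in save_steps)

    dose_counts: dict[int, float] = {}
    for t_j, xi in schedule.events:
        step_j = int(round(t_j / dt))
        if step_j <= n_steps:
            dose_counts[step_j] = dose_counts.get(step_j, 0.0) + xi

    ia1 = REDUCED_INDEX["A_1"]
    ia1ln = REDUCED_INDEX["A1_LN"]
    children = np.random.SeedSequence(seed).spawn(n_reps)
    trajectories: list[Trajectory] = []
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        ens = AgentEnsemble.from_initial(init, params, scalings)
        rows = np.empty((len(save_steps), len(TRAJ_COLUMNS)))
        row = 0
        for step in range(n_steps + 1):
            if step in save_set:
                rows[row] = _expand_reduced(ens.dimensional(), params)
                row += 1
            if step == n_steps:
                break
            xi = dose_counts.get(step)
            if xi is not None:
                new = ens.counts.copy()
                new[ia1] += integer_spawn(xi * params.f_pembro / gamma[ia1], rng)
                new[ia1ln] += integer_spawn(
                    xi * params.f_pembro / gamma[ia1ln], rng
                )
                ens = replace(ens, counts=new)
            ens = abm_step(ens, params, dt, rng)
        manifest = {
            "model": "abm",
            "replicate": k,
            "seed": seed,
            "dt": dt,
            "t_final": t_final,
            "schedule": list(schedule.events),
            "group_sizes": dict(scalings.g),
            "params": params.to_dict(),
        }
        trajectories.append(Trajectory(
            times=save_steps * dt, data=rows,
            kind=f"abm-replicate-{k}", manifest=manifest,
        ))
    return trajectories
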