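"""QSSA-reduced model: 20 slow states, 12 fast species closed algebraically.

Cytokines, the effector CD8/Treg pools in the TDLN, naive macrophages and the
PD-1/drug complexes all relax on timescales much shorter than the slow cell
populations, so each is replaced by the closed form obtained from setting its
balance to zero. The reduced vector field is assembled from a per-capita
process decomposition (:func:`reduced_processes`): every term is either a
zeroth-order source, a per-capita birth, a per-capita loss, or a per-capita
transition with a destination flux factor. The stochastic agent-based
analogue consumes the same decomposition, which makes mean-field agreement
between the two exact by construction.

TGF-beta production uses viable cancer cells and M2 macrophages, matching the
dynamic balance equation in both the dimensional and nondimensional systems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fullmodel import FULL_INDEX, FULL_VARS
from .params import InitialState, ModelParams

__all__ = [
    "REDUCED_VARS",
    "REDUCED_INDEX",
    "FAST_VARS",
    "FastObservables",
    "fast_observables",
    "reduced_processes",
    "rhs_reduced",
    "reduced_initials",
    "embed_reduced",
]

#: Slow states, canonical order.
REDUCED_VARS: tuple[str, ...] = (
    "C", "N_c", "D_0", "D", "D_LN",
    "T0_8", "T_8", "T_ex", "T0_r", "T_r",
    "M_2", "K_0", "K",
    "PD_T8", "PD_K", "A_1", "P_L",
    "PD_8LN", "A1_LN", "PL_LN",
)
REDUCED_INDEX: dict[str, int] = {name: i for i, name in enumerate(REDUCED_VARS)}

#: Species eliminated by the QSSA, in the order of :class:`FastObservables`.
FAST_VARS: tuple[str, ...] = (
    "TA_8", "TA_r", "M_0",
    "I_2", "I_gamma", "I_alpha", "I_beta", "I_10", "I_12",
    "QA_T8", "QA_K", "QA_8LN",
)


@dataclass(frozen=True)
class FastObservables:
    """Closed-form values of the fast species given a slow state."""

    TA_8: float
    TA_r: float
    M_0: float
    I_2: float
    I_gamma: float
    I_alpha: float
    I_beta: float
    I_10: float
    I_12: float
    QA_T8: float
    QA_K: float
    QA_8LN: float
    # PD-1/PD-L1 closures (shared with the full model) kept alongside, since
    # every consumer of the fast state needs them too.
    Q_T8: float
    Q_K: float
    Q_8LN: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FAST_VARS} | {
            "Q_T8": self.Q_T8, "Q_K": self.Q_K, "Q_8LN": self.Q_8LN,
        }


def fast_observables(y: np.ndarray, p: ModelParams) -> FastObservables:
    """Evaluate all twelve fast closed forms on a slow state."""
    (C, N_c, D_0, D, D_LN, T0_8, T_8, T_ex, T0_r, T_r,
     M_2, K_0, K, PD_T8, PD_K, A_1, P_L, PD_8LN, A1_LN, PL_LN) = map(float, y)

    ratio = p.lambda_PDPL / p.lambda_Q
    q_t8 = ratio * PD_T8 * P_L
    q_k = ratio * PD_K * P_L
    q_8ln = ratio * PD_8LN * PL_LN

    # linear cytokine balances: steady state = production / decay
    i2 = p.lambda_I2T8 * T_8 / p.d_I2
    ig = p.lambda_IgK * K / p.d_Ig
    ia = (p.lambda_IaT8 * T_8 + p.lambda_IaK * K) / p.d_Ia
    ib = (p.lambda_IbC * C + p.lambda_IbM2 * M_2) / p.d_Ib
    i10 = p.lambda_I10C * C / p.d_I10
    i12 = p.lambda_I12D * D / p.d_I12

    # naive macrophages: supply over total polarisation + death rate
    m0 = p.A_M0 / (
        p.lambda_M1Ig * ig / (p.K_M1Ig + ig)
        + p.lambda_M1Ia * ia / (p.K_M1Ia + ia)
        + p.lambda_M2Ib * ib / (p.K_M2Ib + ib)
        + p.lambda_M2I10 * i10 / (p.K_M2I10 + i10)
        + p.d_M0
    )

    # effector Tregs in the TDLN: burst size times activation over removal
    # (an exactly zero activation flux short-circuits the division so that
    # degenerate toy settings with zero removal rates stay well defined)
    num_r = (
        2.0 ** p.nr_max * math.exp(-p.d_T0r * p.tau_TAr)
        * p.lambda_T0rTAr * D_LN * T0_r
    )
    tar = num_r / (p.lambda_TArTr + p.d_Tr) if num_r > 0.0 else 0.0

    # effector CD8s in the TDLN: four inhibition divisors (activation and
    # proliferation, each by effector Tregs and by the PD-1/PD-L1 complex)
    num_8 = (
        2.0 ** p.n8_max * math.exp(-p.d_T08 * p.tau_TA8)
        * p.lambda_T08TA8 * D_LN * T0_8
    )
    ta8 = (
        num_8
        / (
            (p.lambda_TA8T8 + p.d_T8)
            * (1.0 + tar / p.K_T08TAr) * (1.0 + q_8ln / p.K_T08Q8LN)
            * (1.0 + tar / p.K_TA8TAr) * (1.0 + q_8ln / p.K_TA8Q8LN)
        )
        if num_8 > 0.0 else 0.0
    )

    # PD-1/drug complexes: association over dissociation + internalisation
    qa_scale = p.lambda_PDA1 / (p.lambda_QA + p.d_QA)
    return FastObservables(
        TA_8=ta8, TA_r=tar, M_0=m0,
        I_2=i2, I_gamma=ig, I_alpha=ia, I_beta=ib, I_10=i10, I_12=i12,
        QA_T8=qa_scale * PD_T8 * A_1,
        QA_K=qa_scale * PD_K * A_1,
        QA_8LN=qa_scale * PD_8LN * A1_LN,
        Q_T8=q_t8, Q_K=q_k, Q_8LN=q_8ln,
    )


@dataclass(frozen=True)
class ReducedProcesses:
    """Per-capita decomposition of the reduced vector field.

    ``sources``: zeroth-order influx (units of the species per cm^3 per day).
    ``births``: per-capita birth rates (1/day), spawning the same species.
    ``losses``: per-capita removal hazards (1/day).
    ``transitions``: (src, dest, per-capita hazard, flux factor). The
    dimensional flux into ``dest`` is factor * hazard * X_src; the factor
    carries burst sizes, transit-survival attenuation and compartment-volume
    ratios.
    """

    fast: FastObservables
    sources: dict[str, float]
    births: dict[str, float]
    losses: dict[str, list[float]]
    transitions: list[tuple[str, str, float, float]]


def reduced_processes(y: np.ndarray, p: ModelParams) -> ReducedProcesses:
    (C, N_c, D_0, D, D_LN, T0_8, T_8, T_ex, T0_r, T_r,
     M_2, K_0, K, PD_T8, PD_K, A_1, P_L, PD_8LN, A1_LN, PL_LN) = map(float, y)
    f = fast_observables(y, p)

    beta_inh = 1.0 + f.I_beta / p.K_CIb
    growth = p.lambda_C * (1.0 - C / p.C_0)
    c_losses = [
        p.lambda_CT8 * T_8 / (beta_inh * (1.0 + f.Q_T8 / p.K_CQT8)),
        p.lambda_CK * K / (beta_inh * (1.0 + f.Q_K / p.K_CQK)),
    ]
    if growth < 0.0:  # above carrying capacity the net logistic term removes
        c_losses.append(-growth)
        growth = 0.0

    a8 = (
        p.lambda_T08TA8 * D_LN
        / ((1.0 + f.TA_r / p.K_T08TAr) * (1.0 + f.Q_8LN / p.K_T08Q8LN))
    )
    m8 = (
        (p.V_LN / p.V_TS)
        * p.lambda_TA8T8 * math.exp(-p.d_T8 * p.tau_a)
        * 2.0 ** p.n8_max * math.exp(-p.d_T08 * p.tau_TA8)
        / (
            (p.lambda_TA8T8 + p.d_T8)
            * (1.0 + f.TA_r / p.K_TA8TAr) * (1.0 + f.Q_8LN / p.K_TA8Q8LN)
        )
        if p.lambda_TA8T8 > 0.0 else 0.0
    )
    ar = p.lambda_T0rTAr * D_LN
    mr = (
        (p.V_LN / p.V_TS)
        * p.lambda_TArTr * math.exp(-p.d_Tr * p.tau_a)
        * 2.0 ** p.nr_max * math.exp(-p.d_T0r * p.tau_TAr)
        / (p.lambda_TArTr + p.d_Tr)
        if p.lambda_TArTr > 0.0 else 0.0
    )

    mu = p.mu_QA
    sources = {
        "D_0": p.A_D0,
        "T0_8": p.A_T08,
        "T0_r": p.A_T0r,
        "K_0": p.A_K0,
        "M_2": f.M_0 * (
            p.lambda_M2Ib * f.I_beta / (p.K_M2Ib + f.I_beta)
            + p.lambda_M2I10 * f.I_10 / (p.K_M2I10 + f.I_10)
        ),
        "PD_T8": p.lambda_PDT8 * T_8,
        "PD_K": p.lambda_PDK * K,
        "P_L": p.lambda_PLC * C + p.lambda_PLM2 * M_2,
        "PD_8LN": p.lambda_PD8LN * f.TA_8,
        "PL_LN": p.lambda_PLLNDLN * D_LN,
    }
    births = {
        "C": growth,
        "T_8": (
            p.lambda_T8I2 * f.I_2 / (p.K_T8I2 + f.I_2)
            / (1.0 + T_r / p.K_T8Tr)
        ),
    }
    losses = {
        "C": c_losses,
        "N_c": [p.d_Nc],
        "D_0": [
            p.lambda_D0K * K / (1.0 + f.I_beta / p.K_D0Ib),
            p.d_D0,
        ],
        "D": [p.d_D],
        "D_LN": [p.d_D],
        "T0_8": [p.d_T08],
        "T_8": [p.d_T8 / (1.0 + f.I_10 / p.K_T8I10)],
        "T_ex": [p.d_Tex / (1.0 + f.I_10 / p.K_TexI10)],
        "T0_r": [p.d_T0r],
        "T_r": [p.d_Tr],
        "M_2": [p.d_M2],
        "K_0": [p.d_K0],
        "K": [p.d_K],
        "PD_T8": [mu * A_1, p.d_PD],
        "PD_K": [mu * A_1, p.d_PD],
        "A_1": [mu * (PD_T8 + PD_K), p.d_A1],
        "P_L": [p.d_PL],
        "PD_8LN": [mu * A1_LN, p.d_PD],
        "A1_LN": [mu * PD_8LN, p.d_A1],
        "PL_LN": [p.d_PL],
    }
    transitions = [
        ("C", "N_c", p.lambda_CIa * f.I_alpha / (p.K_CIa + f.I_alpha), 1.0),
        ("D_0", "D", p.lambda_DNc * N_c / (p.K_DNc + N_c), 1.0),
        (
            "D", "D_LN", p.lambda_DDLN,
            (p.V_TS / p.V_LN) * math.exp(-p.d_D * p.tau_m),
        ),
        ("T0_8", "T_8", a8, m8),
        ("T_8", "T_ex", p.lambda_T8C * C / (p.K_T8C + C), 1.0),
        ("T_ex", "T_8", p.lambda_TexA1 * A_1 / (p.K_TexA1 + A_1), 1.0),
        ("T0_r", "T_r", ar, mr),
        ("K_0", "K", (
            p.lambda_KI2 * f.I_2 / (p.K_KI2 + f.I_2)
            + p.lambda_KI12 * f.I_12 / (p.K_KI12 + f.I_12)
        ) / (1.0 + f.I_beta / p.K_KIb), 1.0),
    ]
    return ReducedProcesses(
        fast=f, sources=sources, births=births, losses=losses,
        transitions=transitions,
    )


def rhs_reduced(t: float, y: np.ndarray, p: ModelParams) -> np.ndarray:
    """Time-derivative of the slow state (per-day rates).

    Drug binding uses the lumped net rate mu_QA = lambda_PDA1 * d_QA /
    (lambda_QA + d_QA); dosing impulses are applied as state jumps by the
    integration driver, not here.
    """
    if np.any(np.isnan(y)):
        raise ValueError(f"NaN in state at t={t}")
    proc = reduced_processes(y, p)
    dy = np.zeros(len(REDUCED_VARS))
    for name, flux in proc.sources.items():
        dy[REDUCED_INDEX[name]] += flux
    for name, rate in proc.births.items():
        i = REDUCED_INDEX[name]
        dy[i] += rate * y[i]
    for name, hazards in proc.losses.items():
        i = REDUCED_INDEX[name]
        dy[i] -= sum(hazards) * y[i]
    for src, dest, hazard, factor in proc.transitions:
        i, j = REDUCED_INDEX[src], REDUCED_INDEX[dest]
        flux = hazard * y[i]
        dy[i] -= flux
        dy[j] += factor * flux
    return dy


def reduced_initials(init: InitialState, p: ModelParams) -> np.ndarray:
    """Slow initial vector: the 20 slow entries of the full initial state.

    Fast species are *not* imposed; they are reported from their closed forms
    thereafter, which generally differ from the tabulated fast initial values
    (the acknowledged QSSA transient discrepancy). Idempotent by construction.
    """
    return np.array([init[name] for name in REDUCED_VARS], dtype=float)


def embed_reduced(y: np.ndarray, p: ModelParams) -> np.ndarray:
    """Embed a slow state into the full 32-state layout, with fast species at
    their QSSA closed forms."""
    f = fast_observables(y, p)
    full = np.empty(len(FULL_VARS))
    for name in REDUCED_VARS:
        full[FULL_INDEX[name]] = y[REDUCED_INDEX[name]]
    for name in FAST_VARS:
        full[FULL_INDEX[name]] = getattr(f, name)
    return full
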