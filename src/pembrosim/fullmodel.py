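"""Right-hand side of the full minimal model.

Thirty-two dynamic states over two well-mixed compartments (tumour site, TS,
and tumour-draining lymph node, TDLN). The short-lived PD-1/PD-L1 complexes
are never integrated: their dissociation rate (1.44 s^-1) puts them on a
sub-second timescale, so they are closed algebraically as bilinear functions
of unbound PD-1 and PD-L1 and substituted into every inhibition term.

State layout is the fixed named ordering ``FULL_VARS`` so that full, reduced
and agent-based outputs are column-compatible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import InitialState, ModelParams

__all__ = [
    "FULL_VARS",
    "FULL_INDEX",
    "OUTPUT_VARS",
    "AlgebraicComplexes",
    "algebraic_complexes",
    "rhs_full",
    "full_initial_vector",
    "total_cancer",
]

#: Dynamic states of the full model, in canonical column order.
FULL_VARS: tuple[str, ...] = (
    "C", "N_c", "D_0", "D", "D_LN",
    "T0_8", "TA_8", "T_8", "T_ex",
    "T0_r", "TA_r", "T_r",
    "M_0", "M_2", "K_0", "K",
    "I_2", "I_gamma", "I_alpha", "I_beta", "I_10", "I_12",
    "PD_T8", "PD_K", "QA_T8", "QA_K", "P_L", "A_1",
    "PD_8LN", "QA_8LN", "PL_LN", "A1_LN",
)

FULL_INDEX: dict[str, int] = {name: i for i, name in enumerate(FULL_VARS)}

#: Reported variables: every dynamic state plus the algebraically closed
#: PD-1/PD-L1 complexes, in the order trajectories are written.
OUTPUT_VARS: tuple[str, ...] = FULL_VARS + ("Q_T8", "Q_K", "Q_8LN")


@dataclass(frozen=True)
class AlgebraicComplexes:
    """QSSA closures and T-cell activation fluxes evaluated on a state.

    ``Q_*`` are the PD-1/PD-L1 complex concentrations (molec/cm^3), bilinear
    in unbound PD-1 and PD-L1 with shared ratio lambda_PDPL / lambda_Q.
    ``R8``/``Rr`` are the DC-driven activation fluxes of naive CD8+ T cells
    and Tregs in the TDLN (cell^2/cm^6); R8 carries the effector-Treg and
    checkpoint inhibition divisors, Treg activation is uninhibited.
    """

    Q_T8: float
    Q_K: float
    Q_8LN: float
    R8: float
    Rr: float


def algebraic_complexes(y: np.ndarray, p: ModelParams) -> AlgebraicComplexes:
    ix = FULL_INDEX
    ratio = p.lambda_PDPL / p.lambda_Q
    q_t8 = ratio * y[ix["PD_T8"]] * y[ix["P_L"]]
    q_k = ratio * y[ix["PD_K"]] * y[ix["P_L"]]
    q_8ln = ratio * y[ix["PD_8LN"]] * y[ix["PL_LN"]]
    r8 = (
        y[ix["D_LN"]] * y[ix["T0_8"]]
        / ((1.0 + y[ix["TA_r"]] / p.K_T08TAr) * (1.0 + q_8ln / p.K_T08Q8LN))
    )
    rr = y[ix["D_LN"]] * y[ix["T0_r"]]
    return AlgebraicComplexes(Q_T8=q_t8, Q_K=q_k, Q_8LN=q_8ln, R8=r8, Rr=rr)


def rhs_full(t: float, y: np.ndarray, p: ModelParams) -> np.ndarray:
    """Time-derivative of the full state (per-day rates).

    Dosing impulses are *not* part of the vector field; infusions are applied
    as instantaneous state jumps by the integration driver.
    """
    if np.any(np.isnan(y)):
        raise ValueError(f"NaN in state at t={t}")
    if np.any(y < 0):
        raise ValueError(f"negative state component at t={t}")

    ix = FULL_INDEX
    (C, N_c, D_0, D, D_LN, T0_8, TA_8, T_8, T_ex, T0_r, TA_r, T_r,
     M_0, M_2, K_0, K, I_2, I_g, I_a, I_b, I_10, I_12,
     PD_T8, PD_K, QA_T8, QA_K, P_L, A_1, PD_8LN, QA_8LN, PL_LN, A1_LN) = y

    cx = algebraic_complexes(y, p)
    dy = np.empty_like(y)

    # viable and necrotic cancer cells
    beta_inh = 1.0 + I_b / p.K_CIb
    kill_t8 = p.lambda_CT8 * T_8 * C / (beta_inh * (1.0 + cx.Q_T8 / p.K_CQT8))
    kill_k = p.lambda_CK * K * C / (beta_inh * (1.0 + cx.Q_K / p.K_CQK))
    necrosis = p.lambda_CIa * I_a / (p.K_CIa + I_a) * C
    dy[ix["C"]] = p.lambda_C * C * (1.0 - C / p.C_0) - kill_t8 - kill_k - necrosis
    dy[ix["N_c"]] = necrosis - p.d_Nc * N_c

    # dendritic cells: DAMP-driven maturation, NK killing of immature DCs,
    # migration of mature DCs to the TDLN with transit attrition
    maturation = p.lambda_DNc * D_0 * N_c / (p.K_DNc + N_c)
    dc_kill = p.lambda_D0K * D_0 * K / (1.0 + I_b / p.K_D0Ib)
    dy[ix["D_0"]] = p.A_D0 - maturation - dc_kill - p.d_D0 * D_0
    dy[ix["D"]] = maturation - p.lambda_DDLN * D - p.d_D * D
    dy[ix["D_LN"]] = (
        (p.V_TS / p.V_LN) * p.lambda_DDLN * np.exp(-p.d_D * p.tau_m) * D
        - p.d_D * D_LN
    )

    # CD8+ lineage: activation in the TDLN, division program with 2^n
    # amplification and exp(-d tau) attrition, egress, IL-2 expansion,
    # exhaustion under chronic antigen exposure, drug reinvigoration
    act8 = p.lambda_T08TA8 * cx.R8
    dy[ix["T0_8"]] = p.A_T08 - act8 - p.d_T08 * T0_8
    prolif8 = (
        2.0 ** p.n8_max * np.exp(-p.d_T08 * p.tau_TA8) * act8
        / ((1.0 + TA_r / p.K_TA8TAr) * (1.0 + cx.Q_8LN / p.K_TA8Q8LN))
    )
    dy[ix["TA_8"]] = prolif8 - p.lambda_TA8T8 * TA_8 - p.d_T8 * TA_8
    migration8 = (
        (p.V_LN / p.V_TS) * p.lambda_TA8T8 * np.exp(-p.d_T8 * p.tau_a) * TA_8
    )
    il2_growth = (
        p.lambda_T8I2 * T_8 * I_2 / (p.K_T8I2 + I_2) / (1.0 + T_r / p.K_T8Tr)
    )
    exhaustion = p.lambda_T8C * T_8 * C / (p.K_T8C + C)
    reinvigoration = p.lambda_TexA1 * T_ex * A_1 / (p.K_TexA1 + A_1)
    dy[ix["T_8"]] = (
        migration8 + il2_growth - exhaustion + reinvigoration
        - p.d_T8 * T_8 / (1.0 + I_10 / p.K_T8I10)
    )
    dy[ix["T_ex"]] = (
        exhaustion - reinvigoration - p.d_Tex * T_ex / (1.0 + I_10 / p.K_TexI10)
    )

    # Treg lineage (activation uninhibited; same program structure)
    actr = p.lambda_T0rTAr * cx.Rr
    dy[ix["T0_r"]] = p.A_T0r - actr - p.d_T0r * T0_r
    prolifr = 2.0 ** p.nr_max * np.exp(-p.d_T0r * p.tau_TAr) * actr
    dy[ix["TA_r"]] = prolifr - p.lambda_TArTr * TA_r - p.d_Tr * TA_r
    dy[ix["T_r"]] = (
        (p.V_LN / p.V_TS) * p.lambda_TArTr * np.exp(-p.d_Tr * p.tau_a) * TA_r
        - p.d_Tr * T_r
    )

    # macrophages: M1 polarisation is a pure drain on the naive pool
    to_m1 = (
        p.lambda_M1Ig * M_0 * I_g / (p.K_M1Ig + I_g)
        + p.lambda_M1Ia * M_0 * I_a / (p.K_M1Ia + I_a)
    )
    to_m2 = (
        p.lambda_M2Ib * M_0 * I_b / (p.K_M2Ib + I_b)
        + p.lambda_M2I10 * M_0 * I_10 / (p.K_M2I10 + I_10)
    )
    dy[ix["M_0"]] = p.A_M0 - to_m1 - to_m2 - p.d_M0 * M_0
    dy[ix["M_2"]] = to_m2 - p.d_M2 * M_2

    # NK cells: IL-2/IL-12 activation inhibited by TGF-beta
    nk_act = (
        (
            p.lambda_KI2 * K_0 * I_2 / (p.K_KI2 + I_2)
            + p.lambda_KI12 * K_0 * I_12 / (p.K_KI12 + I_12)
        )
        / (1.0 + I_b / p.K_KIb)
    )
    dy[ix["K_0"]] = p.A_K0 - nk_act - p.d_K0 * K_0
    dy[ix["K"]] = nk_act - p.d_K * K

    # cytokines: linear production by effector/activated cells, linear decay
    dy[ix["I_2"]] = p.lambda_I2T8 * T_8 - p.d_I2 * I_2
    dy[ix["I_gamma"]] = p.lambda_IgK * K - p.d_Ig * I_g
    dy[ix["I_alpha"]] = p.lambda_IaT8 * T_8 + p.lambda_IaK * K - p.d_Ia * I_a
    dy[ix["I_beta"]] = p.lambda_IbC * C + p.lambda_IbM2 * M_2 - p.d_Ib * I_b
    dy[ix["I_10"]] = p.lambda_I10C * C - p.d_I10 * I_10
    dy[ix["I_12"]] = p.lambda_I12D * D - p.d_I12 * I_12

    # checkpoints and drug, TS: with the PD-1/PD-L1 complex closed
    # algebraically, PD-L1 binding and complex dissociation cancel exactly in
    # the PD-1 and PD-L1 balances, leaving synthesis, drug binding and decay
    dy[ix["PD_T8"]] = (
        p.lambda_PDT8 * T_8 + p.lambda_QA * QA_T8
        - p.lambda_PDA1 * PD_T8 * A_1 - p.d_PD * PD_T8
    )
    dy[ix["PD_K"]] = (
        p.lambda_PDK * K + p.lambda_QA * QA_K
        - p.lambda_PDA1 * PD_K * A_1 - p.d_PD * PD_K
    )
    dy[ix["QA_T8"]] = (
        p.lambda_PDA1 * PD_T8 * A_1 - (p.lambda_QA + p.d_QA) * QA_T8
    )
    dy[ix["QA_K"]] = p.lambda_PDA1 * PD_K * A_1 - (p.lambda_QA + p.d_QA) * QA_K
    dy[ix["P_L"]] = p.lambda_PLC * C + p.lambda_PLM2 * M_2 - p.d_PL * P_L
    dy[ix["A_1"]] = (
        p.lambda_QA * (QA_T8 + QA_K)
        - p.lambda_PDA1 * (PD_T8 + PD_K) * A_1
        - p.d_A1 * A_1
    )

    # checkpoints and drug, TDLN
    dy[ix["PD_8LN"]] = (
        p.lambda_PD8LN * TA_8 + p.lambda_QA * QA_8LN
        - p.lambda_PDA1 * PD_8LN * A1_LN - p.d_PD * PD_8LN
    )
    dy[ix["QA_8LN"]] = (
        p.lambda_PDA1 * PD_8LN * A1_LN - (p.lambda_QA + p.d_QA) * QA_8LN
    )
    dy[ix["PL_LN"]] = p.lambda_PLLNDLN * D_LN - p.d_PL * PL_LN
    dy[ix["A1_LN"]] = (
        p.lambda_QA * QA_8LN
        - p.lambda_PDA1 * PD_8LN * A1_LN
        - p.d_A1 * A1_LN
    )

    return dy


def full_initial_vector(init: InitialState) -> np.ndarray:
    """Initial condition in ``FULL_VARS`` order."""
    return np.array([init[name] for name in FULL_VARS], dtype=float)


def total_cancer(y: np.ndarray, include_necrotic: bool = True) -> float:
    """Total cancer concentration V (cell/cm^3).

    Defined as viable plus necrotic cells; pass ``include_necrotic=False`` to
    report viable cells only. Accepts a state vector (any layout starting
    with C, N_c) or a full trajectory matrix with states in columns.
    """
    arr = np.asarray(y, dtype=float)
    c = arr[..., FULL_INDEX["C"]]
    if not include_necrotic:
        return c
    return c + arr[..., FULL_INDEX["N_c"]]
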