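"""Group-size scalings and the nondimensionalised reduced system.

Each species X is rescaled by a group size g_X via X = g_X * Xtilde. The
substitution is exact for any positive g (no approximation is introduced),
and the rescaled rate constants below are pure combinations of dimensional
constants and g-ratios. The standard recipe ties g_X to the baseline state so
that one agent of the stochastic analogue represents a fixed fraction of the
initial population: 1/5000 of viable cancer cells, 1/2000 of most cell
species, 1/1000 of checkpoint pools, with g = 1 for the algebraically closed
fast species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fullmodel import OUTPUT_VARS
from .params import InitialState, ModelParams
from .reduced import REDUCED_INDEX, REDUCED_VARS

__all__ = [
    "TS_SPECIES",
    "LN_SPECIES",
    "ScalingSet",
    "make_scalings",
    "NondimParams",
    "rescale_params",
    "rhs_reduced_nondim",
]

#: Compartment membership for every reported variable.
LN_SPECIES: frozenset[str] = frozenset({
    "D_LN", "T0_8", "TA_8", "T0_r", "TA_r",
    "PD_8LN", "QA_8LN", "PL_LN", "Q_8LN", "A1_LN",
})
TS_SPECIES: frozenset[str] = frozenset(OUTPUT_VARS) - LN_SPECIES

#: Species whose group size is 1 (fast species and bilinear complexes).
_UNIT_G: tuple[str, ...] = (
    "TA_8", "TA_r", "M_0", "I_2", "I_gamma", "I_alpha", "I_beta", "I_10",
    "I_12", "QA_T8", "Q_T8", "QA_K", "Q_K", "QA_8LN", "Q_8LN",
)
#: Tumour-site cell species grouped at 1/2000 of the initial population.
_TS_CELLS_2000: tuple[str, ...] = (
    "D_0", "D", "T_8", "T_ex", "T_r", "M_2", "K_0", "K",
)
#: Tumour-site checkpoint pools grouped at 1/1000.
_TS_CHECKPOINT_1000: tuple[str, ...] = ("PD_T8", "PD_K", "P_L")

#: Reference free-drug concentration (molec/cm^3) anchoring the drug group
#: size; of the order of the peak concentration after a 200 mg bolus.
DRUG_REFERENCE_CONC = 3.0e14


@dataclass(frozen=True)
class ScalingSet:
    """Group size g_X for every reported species (species units per agent,
    times the compartment volume in the standard recipe)."""

    g: dict[str, float]

    def __post_init__(self):
        missing = set(OUTPUT_VARS) - set(self.g)
        if missing:
            raise ValueError(f"missing group sizes for {sorted(missing)}")
        bad = [k for k, v in self.g.items() if not (v > 0 and math.isfinite(v))]
        if bad:
            raise ValueError(f"group sizes must be positive and finite: {bad}")

    def __getitem__(self, name: str) -> float:
        return self.g[name]

    @classmethod
    def identity(cls) -> "ScalingSet":
        return cls(g={name: 1.0 for name in OUTPUT_VARS})

    def per_agent(self, p: ModelParams) -> "ScalingSet":
        """Divide each group size by its compartment volume, giving the
        concentration represented by one agent. With the standard recipe this
        makes the nondimensional state an integer-valued whole-compartment
        count (5000 initial cancer agents, and so on)."""
        return ScalingSet(g={
            name: v / (p.V_LN if name in LN_SPECIES else p.V_TS)
            for name, v in self.g.items()
        })

    def reduced_vector(self) -> np.ndarray:
        return np.array([self.g[name] for name in REDUCED_VARS])


def make_scalings(init: InitialState, p: ModelParams) -> ScalingSet:
    """The standard group-size recipe, anchored to the initial state."""
    g: dict[str, float] = {name: 1.0 for name in _UNIT_G}

    def anchored(name: str, denom: float, volume: float) -> float:
        x0 = init[name]
        if x0 <= 0:
            raise ValueError(
                f"cannot build a group size for {name}: initial value is 0"
            )
        return x0 * volume / denom

    for name in _TS_CELLS_2000:
        g[name] = anchored(name, 2000.0, p.V_TS)
    for name in _TS_CHECKPOINT_1000:
        g[name] = anchored(name, 1000.0, p.V_TS)
    g["C"] = anchored("C", 5000.0, p.V_TS)
    g["N_c"] = anchored("N_c", 2000.0, p.V_TS)
    g["A_1"] = DRUG_REFERENCE_CONC * p.V_TS / 1000.0
    g["D_LN"] = anchored("D_LN", 1000.0, p.V_LN)
    g["T0_8"] = anchored("T0_8", 2000.0, p.V_LN)
    g["T0_r"] = anchored("T0_r", 2000.0, p.V_LN)
    g["PD_8LN"] = anchored("PD_8LN", 1000.0, p.V_LN)
    g["PL_LN"] = anchored("PL_LN", 1000.0, p.V_LN)
    g["A1_LN"] = DRUG_REFERENCE_CONC * p.V_LN / 1000.0
    return ScalingSet(g=g)


@dataclass(frozen=True)
class NondimParams:
    """Rescaled (tilde/hat) rate constants plus the untouched dimensional
    parameters they are combined with. With all g = 1 every rescaled entry
    equals its dimensional counterpart."""

    params: ModelParams
    scalings: ScalingSet
    values: dict[str, float]

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def rescale_params(p: ModelParams, s: ScalingSet) -> NondimParams:
    g = s.g
    mu = p.mu_QA
    v: dict[str, float] = {
        "Ct_0": p.C_0 / g["C"],
        "lt_CT8": p.lambda_CT8 * g["T_8"],
        "Kt_CIb": p.K_CIb / g["I_beta"],
        "Kt_CQT8": p.K_CQT8 / g["Q_T8"],
        "lt_CK": p.lambda_CK * g["K"],
        "Kt_CQK": p.K_CQK / g["Q_K"],
        "Kt_CIa": p.K_CIa / g["I_alpha"],
        "lt_CIa": p.lambda_CIa * g["C"] / g["N_c"],
        "At_D0": p.A_D0 / g["D_0"],
        "Kt_DNc": p.K_DNc / g["N_c"],
        "lt_D0K": p.lambda_D0K * g["K"],
        "Kt_D0Ib": p.K_D0Ib / g["I_beta"],
        "lt_DNc": p.lambda_DNc * g["D_0"] / g["D"],
        "lt_DDLN": p.lambda_DDLN * g["D"] / g["D_LN"],
        "At_T08": p.A_T08 / g["T0_8"],
        "lt_T08TA8": p.lambda_T08TA8 * g["D_LN"],
        "Kt_T08TAr": p.K_T08TAr / g["TA_r"],
        "Kt_T08Q8LN": p.K_T08Q8LN / g["Q_8LN"],
        "lh_T08TA8": p.lambda_T08TA8 * g["D_LN"] * g["T0_8"] / g["TA_8"],
        "Kt_TA8TAr": p.K_TA8TAr / g["TA_r"],
        "Kt_TA8Q8LN": p.K_TA8Q8LN / g["Q_8LN"],
        "lt_TA8T8": p.lambda_TA8T8 * g["TA_8"] / g["T_8"],
        "Kt_T8I2": p.K_T8I2 / g["I_2"],
        "Kt_T8Tr": p.K_T8Tr / g["T_r"],
        "Kt_T8C": p.K_T8C / g["C"],
        "lt_TexA1": p.lambda_TexA1 * g["T_ex"] / g["T_8"],
        "Kt_TexA1": p.K_TexA1 / g["A_1"],
        "Kt_T8I10": p.K_T8I10 / g["I_10"],
        "lt_T8C": p.lambda_T8C * g["T_8"] / g["T_ex"],
        "Kt_TexI10": p.K_TexI10 / g["I_10"],
        "At_T0r": p.A_T0r / g["T0_r"],
        "lt_T0rTAr": p.lambda_T0rTAr * g["D_LN"],
        "lh_T0rTAr": p.lambda_T0rTAr * g["D_LN"] * g["T0_r"] / g["TA_r"],
        "lt_TArTr": p.lambda_TArTr * g["TA_r"] / g["T_r"],
        "At_M0": p.A_M0 / g["M_0"],
        "Kt_M2Ib": p.K_M2Ib / g["I_beta"],
        "Kt_M1Ig": p.K_M1Ig / g["I_gamma"],
        "Kt_M1Ia": p.K_M1Ia / g["I_alpha"],
        "Kt_M2I10": p.K_M2I10 / g["I_10"],
        "lt_M2Ib": p.lambda_M2Ib * g["M_0"] / g["M_2"],
        "lt_M2I10": p.lambda_M2I10 * g["M_0"] / g["M_2"],
        "At_K0": p.A_K0 / g["K_0"],
        "Kt_KI2": p.K_KI2 / g["I_2"],
        "Kt_KI12": p.K_KI12 / g["I_12"],
        "Kt_KIb": p.K_KIb / g["I_beta"],
        "lt_KI2": p.lambda_KI2 * g["K_0"] / g["K"],
        "lt_KI12": p.lambda_KI12 * g["K_0"] / g["K"],
        "lt_I2T8": p.lambda_I2T8 * g["T_8"] / g["I_2"],
        "lt_IgK": p.lambda_IgK * g["K"] / g["I_gamma"],
        "lt_IaT8": p.lambda_IaT8 * g["T_8"] / g["I_alpha"],
        "lt_IaK": p.lambda_IaK * g["K"] / g["I_alpha"],
        "lt_IbC": p.lambda_IbC * g["C"] / g["I_beta"],
        "lt_IbM2": p.lambda_IbM2 * g["M_2"] / g["I_beta"],
        "lt_I10C": p.lambda_I10C * g["C"] / g["I_10"],
        "lt_I12D": p.lambda_I12D * g["D"] / g["I_12"],
        "lt_PDT8": p.lambda_PDT8 * g["T_8"] / g["PD_T8"],
        "lt_PDK": p.lambda_PDK * g["K"] / g["PD_K"],
        # lumped net drug-binding constants (complex QSSA already applied)
        "l_PDT8A1": mu * g["A_1"],
        "l_PDKA1": mu * g["A_1"],
        "lh_PDT8A1": p.lambda_PDA1 * g["PD_T8"] * g["A_1"] / g["QA_T8"],
        "lh_PDKA1": p.lambda_PDA1 * g["PD_K"] * g["A_1"] / g["QA_K"],
        "f_pembroA1": p.f_pembro / g["A_1"],
        "lt_PDT8A1": mu * g["PD_T8"],
        "lt_PDKA1": mu * g["PD_K"],
        "lt_PLC": p.lambda_PLC * g["C"] / g["P_L"],
        "lt_PLM2": p.lambda_PLM2 * g["M_2"] / g["P_L"],
        "l_PDT8PL": p.lambda_PDPL * g["PD_T8"] * g["P_L"] / g["Q_T8"],
        "l_PDKPL": p.lambda_PDPL * g["PD_K"] * g["P_L"] / g["Q_K"],
        "lt_PD8LN": p.lambda_PD8LN * g["TA_8"] / g["PD_8LN"],
        "l_PD8LNA1LN": mu * g["A1_LN"],
        "lh_PD8LNA1LN": p.lambda_PDA1 * g["PD_8LN"] * g["A1_LN"] / g["QA_8LN"],
        "f_pembroA1LN": p.f_pembro / g["A1_LN"],
        "lt_PD8LNA1LN": mu * g["PD_8LN"],
        "lt_PLLNDLN": p.lambda_PLLNDLN * g["D_LN"] / g["PL_LN"],
        "l_PD8LNPLLN": p.lambda_PDPL * g["PD_8LN"] * g["PL_LN"] / g["Q_8LN"],
    }
    return NondimParams(params=p, scalings=s, values=v)


def rhs_reduced_nondim(t: float, yt: np.ndarray, np_: NondimParams) -> np.ndarray:
    """Reduced vector field in rescaled variables, written directly from the
    tilde/hat parameters (not by delegating to the dimensional system), so
    the change-of-variables identity g * f_tilde(y / g) = f(y) is a genuine
    cross-check between two independently coded right-hand sides."""
    p = np_.params
    v = np_.values
    (C, N_c, D_0, D, D_LN, T0_8, T_8, T_ex, T0_r, T_r,
     M_2, K_0, K, PD_T8, PD_K, A_1, P_L, PD_8LN, A1_LN, PL_LN) = map(float, yt)

    q_t8 = v["l_PDT8PL"] / p.lambda_Q * PD_T8 * P_L
    q_k = v["l_PDKPL"] / p.lambda_Q * PD_K * P_L
    q_8ln = v["l_PD8LNPLLN"] / p.lambda_Q * PD_8LN * PL_LN

    i2 = v["lt_I2T8"] / p.d_I2 * T_8
    ig = v["lt_IgK"] / p.d_Ig * K
    ia = (v["lt_IaT8"] * T_8 + v["lt_IaK"] * K) / p.d_Ia
    ib = (v["lt_IbC"] * C + v["lt_IbM2"] * M_2) / p.d_Ib
    i10 = v["lt_I10C"] / p.d_I10 * C
    i12 = v["lt_I12D"] / p.d_I12 * D

    tar = (
        2.0 ** p.nr_max * math.exp(-p.d_T0r * p.tau_TAr)
        * v["lh_T0rTAr"] * D_LN * T0_r
        / (p.lambda_TArTr + p.d_Tr)
    )
    r8 = D_LN * T0_8 / (
        (1.0 + tar / v["Kt_T08TAr"]) * (1.0 + q_8ln / v["Kt_T08Q8LN"])
    )
    ta8 = (
        2.0 ** p.n8_max * math.exp(-p.d_T08 * p.tau_TA8) * v["lh_T08TA8"] * r8
        / (
            (p.lambda_TA8T8 + p.d_T8)
            * (1.0 + tar / v["Kt_TA8TAr"]) * (1.0 + q_8ln / v["Kt_TA8Q8LN"])
        )
    )
    m0 = v["At_M0"] / (
        p.lambda_M1Ig * ig / (v["Kt_M1Ig"] + ig)
        + p.lambda_M1Ia * ia / (v["Kt_M1Ia"] + ia)
        + p.lambda_M2Ib * ib / (v["Kt_M2Ib"] + ib)
        + p.lambda_M2I10 * i10 / (v["Kt_M2I10"] + i10)
        + p.d_M0
    )

    dy = np.empty(len(REDUCED_VARS))
    ix = REDUCED_INDEX
    beta_inh = 1.0 + ib / v["Kt_CIb"]
    dy[ix["C"]] = (
        p.lambda_C * C * (1.0 - C / v["Ct_0"])
        - v["lt_CT8"] * T_8 * C / (beta_inh * (1.0 + q_t8 / v["Kt_CQT8"]))
        - v["lt_CK"] * K * C / (beta_inh * (1.0 + q_k / v["Kt_CQK"]))
        - p.lambda_CIa * ia / (v["Kt_CIa"] + ia) * C
    )
    dy[ix["N_c"]] = v["lt_CIa"] * ia / (v["Kt_CIa"] + ia) * C - p.d_Nc * N_c
    dy[ix["D_0"]] = (
        v["At_D0"]
        - p.lambda_DNc * D_0 * N_c / (v["Kt_DNc"] + N_c)
        - v["lt_D0K"] * D_0 * K / (1.0 + ib / v["Kt_D0Ib"])
        - p.d_D0 * D_0
    )
    dy[ix["D"]] = (
        v["lt_DNc"] * D_0 * N_c / (v["Kt_DNc"] + N_c)
        - p.lambda_DDLN * D - p.d_D * D
    )
    dy[ix["D_LN"]] = (
        (p.V_TS / p.V_LN) * v["lt_DDLN"] * math.exp(-p.d_D * p.tau_m) * D
        - p.d_D * D_LN
    )
    dy[ix["T0_8"]] = v["At_T08"] - v["lt_T08TA8"] * r8 - p.d_T08 * T0_8
    dy[ix["T_8"]] = (
        (p.V_LN / p.V_TS) * v["lt_TA8T8"] * math.exp(-p.d_T8 * p.tau_a) * ta8
        + p.lambda_T8I2 * T_8 * i2 / (v["Kt_T8I2"] + i2)
        / (1.0 + T_r / v["Kt_T8Tr"])
        - p.lambda_T8C * T_8 * C / (v["Kt_T8C"] + C)
        + v["lt_TexA1"] * T_ex * A_1 / (v["Kt_TexA1"] + A_1)
        - p.d_T8 * T_8 / (1.0 + i10 / v["Kt_T8I10"])
    )
    dy[ix["T_ex"]] = (
        v["lt_T8C"] * T_8 * C / (v["Kt_T8C"] + C)
        - p.lambda_TexA1 * T_ex * A_1 / (v["Kt_TexA1"] + A_1)
        - p.d_Tex * T_ex / (1.0 + i10 / v["Kt_TexI10"])
    )
    dy[ix["T0_r"]] = v["At_T0r"] - v["lt_T0rTAr"] * D_LN * T0_r - p.d_T0r * T0_r
    dy[ix["T_r"]] = (
        (p.V_LN / p.V_TS) * v["lt_TArTr"] * math.exp(-p.d_Tr * p.tau_a) * tar
        - p.d_Tr * T_r
    )
    dy[ix["M_2"]] = (
        v["lt_M2Ib"] * m0 * ib / (v["Kt_M2Ib"] + ib)
        + v["lt_M2I10"] * m0 * i10 / (v["Kt_M2I10"] + i10)
        - p.d_M2 * M_2
    )
    nk_drive_loss = (
        p.lambda_KI2 * K_0 * i2 / (v["Kt_KI2"] + i2)
        + p.lambda_KI12 * K_0 * i12 / (v["Kt_KI12"] + i12)
    ) / (1.0 + ib / v["Kt_KIb"])
    nk_drive_gain = (
        v["lt_KI2"] * K_0 * i2 / (v["Kt_KI2"] + i2)
        + v["lt_KI12"] * K_0 * i12 / (v["Kt_KI12"] + i12)
    ) / (1.0 + ib / v["Kt_KIb"])
    dy[ix["K_0"]] = v["At_K0"] - nk_drive_loss - p.d_K0 * K_0
    dy[ix["K"]] = nk_drive_gain - p.d_K * K
    dy[ix["PD_T8"]] = (
        v["lt_PDT8"] * T_8 - v["l_PDT8A1"] * PD_T8 * A_1 - p.d_PD * PD_T8
    )
    dy[ix["PD_K"]] = (
        v["lt_PDK"] * K - v["l_PDKA1"] * PD_K * A_1 - p.d_PD * PD_K
    )
    dy[ix["A_1"]] = (
        -(v["lt_PDT8A1"] * PD_T8 + v["lt_PDKA1"] * PD_K) * A_1
        - p.d_A1 * A_1
    )
    dy[ix["P_L"]] = v["lt_PLC"] * C + v["lt_PLM2"] * M_2 - p.d_PL * P_L
    dy[ix["PD_8LN"]] = (
        v["lt_PD8LN"] * ta8 - v["l_PD8LNA1LN"] * PD_8LN * A1_LN
        - p.d_PD * PD_8LN
    )
    dy[ix["A1_LN"]] = (
        -v["lt_PD8LNA1LN"] * PD_8LN * A1_LN - p.d_A1 * A1_LN
    )
    dy[ix["PL_LN"]] = v["lt_PLLNDLN"] * D_LN - p.d_PL * PL_LN
    return dy
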