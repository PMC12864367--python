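"""Shared fixtures: packaged defaults and explicit toy configurations.

Toy parameter sets use order-one magnitudes so analytic expectations are easy
to state; the ``stiff`` variant separates fast and slow rates by more than
two orders of magnitude, the regime the quasi-steady-state reduction assumes.
"""

from __future__ import annotations

import numpy as np
import pytest

from pembrosim.params import (
    InitialState,
    ModelParams,
    default_params,
    params_from_mapping,
)

# order-one toy configuration; fast processes (cytokine turnover, TDLN
# effector-pool removal, naive-macrophage drain, drug-complex turnover) sit
# at rate >= 50/day against slow rates <= 0.4/day
TOY_PARAMS: dict[str, float] = {
    "lambda_C": 0.4, "C_0": 50.0,
    "lambda_CT8": 0.05, "lambda_CK": 0.05, "lambda_CIa": 0.3,
    "K_CIb": 1.0, "K_CQT8": 1.0, "K_CQK": 1.0, "K_CIa": 1.0, "d_Nc": 0.4,
    "A_D0": 0.5, "lambda_DNc": 0.4, "K_DNc": 1.0,
    "lambda_D0K": 0.05, "K_D0Ib": 1.0, "lambda_DDLN": 0.3,
    "d_D0": 0.2, "d_D": 0.2, "tau_m": 0.2,
    "A_T08": 0.5, "lambda_T08TA8": 0.1,
    "K_T08TAr": 1.0, "K_TA8TAr": 1.0, "K_T08Q8LN": 1.0, "K_TA8Q8LN": 1.0,
    "n8_max": 3, "Delta8_0": 0.5, "Delta8": 0.25, "d_T08": 0.1,
    "lambda_TA8T8": 50.0, "tau_a": 0.1,
    "lambda_T8I2": 0.2, "K_T8I2": 1.0, "K_T8Tr": 1.0,
    "lambda_T8C": 0.3, "K_T8C": 1.0,
    "lambda_TexA1": 0.3, "K_TexA1": 1.0,
    "d_T8": 0.3, "d_Tex": 0.3, "K_T8I10": 1.0, "K_TexI10": 1.0,
    "A_T0r": 0.3, "lambda_T0rTAr": 0.1, "nr_max": 2,
    "Deltar_0": 0.5, "Deltar": 0.25, "d_T0r": 0.1,
    "lambda_TArTr": 50.0, "d_Tr": 0.3,
    "A_M0": 5.0,
    "lambda_M1Ig": 10.0, "K_M1Ig": 1.0, "lambda_M1Ia": 10.0, "K_M1Ia": 1.0,
    "lambda_M2Ib": 10.0, "K_M2Ib": 1.0, "lambda_M2I10": 10.0, "K_M2I10": 1.0,
    "d_M0": 50.0, "d_M2": 0.3,
    "A_K0": 0.5, "lambda_KI2": 0.3, "K_KI2": 1.0,
    "lambda_KI12": 0.3, "K_KI12": 1.0, "K_KIb": 1.0,
    "d_K0": 0.2, "d_K": 0.2,
    "lambda_I2T8": 50.0, "lambda_IgK": 50.0, "lambda_IaT8": 50.0,
    "lambda_IaK": 50.0, "lambda_IbC": 50.0, "lambda_IbM2": 50.0,
    "lambda_I10C": 50.0, "lambda_I12D": 50.0,
    "d_I2": 100.0, "d_Ig": 100.0, "d_Ia": 100.0, "d_Ib": 100.0,
    "d_I10": 100.0, "d_I12": 100.0,
    "lambda_PDT8": 100.0, "lambda_PDK": 100.0, "lambda_PD8LN": 100.0,
    "lambda_PDA1": 0.2, "lambda_PDPL": 0.1,
    "lambda_QA": 50.0, "lambda_Q": 1000.0, "d_QA": 50.0,
    "d_PD": 1.0, "d_PL": 1.0, "d_A1": 0.2,
    "lambda_PLC": 100.0, "lambda_PLM2": 100.0, "lambda_PLLNDLN": 100.0,
    "f_pembro": 1.0,
    "V_TS": 2.0, "V_LN": 1.0,
}

TOY_INIT: dict[str, float] = {
    "C": 5.0, "N_c": 1.0, "D_0": 1.0, "D": 1.0, "D_LN": 1.0,
    "T0_8": 2.0, "TA_8": 0.5, "T_8": 1.0, "T_ex": 0.5,
    "T0_r": 1.0, "TA_r": 0.5, "T_r": 0.5,
    "M_0": 0.2, "M_2": 0.5, "K_0": 1.0, "K": 1.0,
    "I_2": 0.5, "I_gamma": 0.5, "I_alpha": 1.0, "I_beta": 0.5,
    "I_10": 0.5, "I_12": 0.5,
    "PD_T8": 100.0, "PD_K": 100.0, "P_L": 500.0,
    "PD_8LN": 100.0, "PL_LN": 100.0,
    "QA_T8": 0.0, "QA_K": 0.0, "QA_8LN": 0.0, "A_1": 0.0, "A1_LN": 0.0,
}


def make_toy_params(**overrides) -> ModelParams:
    mapping = {**TOY_PARAMS, **overrides}
    allow_zero = [k for k, v in mapping.items() if v == 0]
    return params_from_mapping(mapping, allow_zero=allow_zero)


@pytest.fixture(scope="session")
def defaults() -> ModelParams:
    return default_params()


@pytest.fixture(scope="session")
def default_init() -> InitialState:
    return InitialState.default()


@pytest.fixture()
def toy_params() -> ModelParams:
    return make_toy_params()


@pytest.fixture()
def toy_init() -> InitialState:
    return InitialState.from_mapping(TOY_INIT)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
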