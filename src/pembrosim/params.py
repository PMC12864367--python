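"""Model constants, initial conditions and dose schedules.

Units are fixed package-wide: time in day, volumes in cm^3, cell densities in
cell/cm^3, cytokines in g/cm^3, checkpoint species and drug in molec/cm^3,
doses in mg. There is no unit-conversion layer.

Parameter files are flat ASCII ``symbol: value`` YAML maps, one key per rate
constant, so they diff and grep cleanly against the model equations.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "ModelParams",
    "InitialState",
    "DoseSchedule",
    "load_params",
    "save_params",
    "default_params",
    "division_program_duration",
    "survival_factor",
    "build_schedule",
    "dose_per_kg",
    "TABLE_TS_CHECKPOINT_INIT",
    "TABLE_TDLN_CHECKPOINT_INIT",
]

_INTEGER_FIELDS = frozenset({"n8_max", "nr_max"})


def division_program_duration(delta0: float, delta: float, n_max: int) -> float:
    """Duration of a T-cell division program.

    A cell activated in the lymph node divides ``n_max`` times; the first
    cycle takes ``delta0`` days and each subsequent cycle ``delta`` days, so
    the program lasts ``delta0 + (n_max - 1) * delta`` days.
    """
    if n_max < 1:
        raise ValueError(f"n_max must be >= 1, got {n_max}")
    if delta0 < 0 or delta < 0:
        raise ValueError("cycle times must be non-negative")
    return delta0 + (n_max - 1) * delta


def survival_factor(d: float, tau: float) -> float:
    """Fraction exp(-d*tau) of cells surviving a fixed lag of ``tau`` days
    under a constant per-capita death rate ``d`` (1/day)."""
    if d < 0 or tau < 0:
        raise ValueError("death rate and lag must be non-negative")
    return math.exp(-d * tau)


@dataclass(frozen=True)
class ModelParams:
    """Every dimensional constant of the minimal two-compartment model.

    Fields are keyed by ASCII-canonical symbol names (``lambda_CT8`` for the
    CD8-mediated lysis rate, ``K_CIb`` for the TGF-beta inhibition constant of
    cancer lysis, ...). ``A_*`` are supply rates, ``lambda_*`` kinetic rate
    constants, ``K_*`` Michaelis/inhibition constants, ``d_*`` decay rates.
    """

    # -- viable cancer cells: logistic growth and three elimination channels
    lambda_C: float      # 1/day, intrinsic growth rate
    C_0: float           # cell/cm^3, carrying capacity
    lambda_CT8: float    # cm^3/cell/day, lysis by effector CD8+ T cells
    lambda_CK: float     # cm^3/cell/day, lysis by activated NK cells
    lambda_CIa: float    # 1/day, TNF-driven necroptosis (saturating)
    K_CIb: float         # g/cm^3, TGF-beta inhibition of lysis
    K_CQT8: float        # molec/cm^3, PD-1/PD-L1 inhibition of CD8 lysis
    K_CQK: float         # molec/cm^3, PD-1/PD-L1 inhibition of NK lysis
    K_CIa: float         # g/cm^3, half-saturation of TNF necroptosis
    d_Nc: float          # 1/day, necrotic debris removal

    # -- dendritic cells
    A_D0: float          # cell/cm^3/day, immature DC supply
    lambda_DNc: float    # 1/day, DAMP-driven maturation (saturating in N_c)
    K_DNc: float         # cell/cm^3
    lambda_D0K: float    # cm^3/cell/day, NK killing of immature DCs
    K_D0Ib: float        # g/cm^3, TGF-beta inhibition of that killing
    lambda_DDLN: float   # 1/day, mature DC migration to the TDLN
    d_D0: float          # 1/day
    d_D: float           # 1/day
    tau_m: float         # day, DC migration lag

    # -- CD8+ T-cell lineage
    A_T08: float         # cell/cm^3/day, naive CD8 supply into the TDLN
    lambda_T08TA8: float  # cm^3/cell/day, activation by mature DCs
    K_T08TAr: float      # cell/cm^3, Treg inhibition of activation
    K_TA8TAr: float      # cell/cm^3, Treg inhibition of proliferation
    K_T08Q8LN: float     # molec/cm^3, PD-1/PD-L1 inhibition of activation
    K_TA8Q8LN: float     # molec/cm^3, PD-1/PD-L1 inhibition of proliferation
    n8_max: int          # divisions in the CD8 program
    Delta8_0: float      # day, first cycle time
    Delta8: float        # day, later cycle times
    d_T08: float         # 1/day, death of naive/dividing CD8s
    lambda_TA8T8: float  # 1/day, effector CD8 egress to the TS
    tau_a: float         # day, TDLN -> TS migration lag
    lambda_T8I2: float   # 1/day, IL-2-driven CTL expansion (saturating)
    K_T8I2: float        # g/cm^3
    K_T8Tr: float        # cell/cm^3, Treg inhibition of expansion
    lambda_T8C: float    # 1/day, exhaustion under chronic antigen exposure
    K_T8C: float         # cell/cm^3
    lambda_TexA1: float  # 1/day, pembrolizumab reinvigoration of T_ex
    K_TexA1: float       # molec/cm^3
    d_T8: float          # 1/day
    d_Tex: float         # 1/day
    K_T8I10: float       # g/cm^3, IL-10 inhibition of CTL death
    K_TexI10: float      # g/cm^3

    # -- Treg lineage
    A_T0r: float         # cell/cm^3/day
    lambda_T0rTAr: float  # cm^3/cell/day
    nr_max: int
    Deltar_0: float      # day
    Deltar: float        # day
    d_T0r: float         # 1/day
    lambda_TArTr: float  # 1/day, effector Treg egress to the TS
    d_Tr: float          # 1/day

    # -- macrophages
    A_M0: float          # cell/cm^3/day
    lambda_M1Ig: float   # 1/day, IFN-gamma-driven M1 polarisation (drain)
    K_M1Ig: float        # g/cm^3
    lambda_M1Ia: float   # 1/day, TNF-driven M1 polarisation (drain)
    K_M1Ia: float        # g/cm^3
    lambda_M2Ib: float   # 1/day, TGF-beta-driven M2 polarisation
    K_M2Ib: float        # g/cm^3
    lambda_M2I10: float  # 1/day, IL-10-driven M2 polarisation
    K_M2I10: float       # g/cm^3
    d_M0: float          # 1/day
    d_M2: float          # 1/day

    # -- NK cells
    A_K0: float          # cell/cm^3/day
    lambda_KI2: float    # 1/day, IL-2 activation
    K_KI2: float         # g/cm^3
    lambda_KI12: float   # 1/day, IL-12 activation
    K_KI12: float        # g/cm^3
    K_KIb: float         # g/cm^3, TGF-beta inhibition of activation
    d_K0: float          # 1/day
    d_K: float           # 1/day

    # -- cytokines (mass-action production per producing cell, linear decay)
    lambda_I2T8: float   # g/cell/day
    lambda_IgK: float    # g/cell/day
    lambda_IaT8: float   # g/cell/day
    lambda_IaK: float    # g/cell/day
    lambda_IbC: float    # g/cell/day
    lambda_IbM2: float   # g/cell/day
    lambda_I10C: float   # g/cell/day
    lambda_I12D: float   # g/cell/day
    d_I2: float          # 1/day
    d_Ig: float          # 1/day
    d_Ia: float          # 1/day
    d_Ib: float          # 1/day
    d_I10: float         # 1/day
    d_I12: float         # 1/day

    # -- immune checkpoints and pembrolizumab
    lambda_PDT8: float   # molec/cell/day, PD-1 synthesis on TS CD8s
    lambda_PDK: float    # molec/cell/day, PD-1 synthesis on activated NKs
    lambda_PD8LN: float  # molec/cell/day, PD-1 synthesis on TDLN CD8s
    lambda_PDA1: float   # cm^3/molec/day, PD-1 + drug association
    lambda_PDPL: float   # cm^3/molec/day, PD-1 + PD-L1 association
    lambda_QA: float     # 1/day, PD-1/drug complex dissociation
    lambda_Q: float      # 1/day, PD-1/PD-L1 complex dissociation
    d_QA: float          # 1/day, PD-1/drug complex internalisation
    d_PD: float          # 1/day
    d_PL: float          # 1/day
    d_A1: float          # 1/day, drug elimination
    lambda_PLC: float    # molec/cell/day, PD-L1 synthesis by cancer cells
    lambda_PLM2: float   # molec/cell/day, PD-L1 synthesis by M2 macrophages
    lambda_PLLNDLN: float  # molec/cell/day, PD-L1 synthesis by TDLN DCs
    f_pembro: float      # molec/cm^3 per mg, dose-to-concentration scaling

    # -- compartment volumes
    V_TS: float          # cm^3, tumour site
    V_LN: float          # cm^3, tumour-draining lymph node

    @property
    def tau_TA8(self) -> float:
        """CD8 division-program duration (derived, never stored)."""
        return division_program_duration(self.Delta8_0, self.Delta8, self.n8_max)

    @property
    def tau_TAr(self) -> float:
        """Treg division-program duration (derived, never stored)."""
        return division_program_duration(self.Deltar_0, self.Deltar, self.nr_max)

    @property
    def mu_QA(self) -> float:
        """Lumped net drug-binding rate lambda_PDA1 * d_QA / (lambda_QA + d_QA).

        Under the PD-1/drug-complex QSSA, dissociating complexes return drug
        and receptor, so only the internalised fraction is a net loss.
        """
        return self.lambda_PDA1 * self.d_QA / (self.lambda_QA + self.d_QA)

    def validate(self, allow_zero: Iterable[str] = ()) -> None:
        """Check signs and integrality; ``allow_zero`` names fields for which
        a zero value is an admissible toy setting."""
        zero_ok = set(allow_zero)
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name in _INTEGER_FIELDS:
                if int(v) != v or v < 1:
                    raise ValueError(f"{f.name} must be a positive integer, got {v}")
                continue
            if not math.isfinite(v):
                raise ValueError(f"{f.name} must be finite, got {v}")
            if v < 0 or (v == 0 and f.name not in zero_ok):
                raise ValueError(f"parameter {f.name} must be > 0, got {v}")

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}


PARAM_NAMES: tuple[str, ...] = tuple(
    f.name for f in dataclasses.fields(ModelParams)
)


def _coerce(name: str, value) -> float | int:
    if name in _INTEGER_FIELDS:
        return int(value)
    return float(value)


def load_params(path: str | Path, allow_zero: Iterable[str] = ()) -> ModelParams:
    """Load and validate a flat YAML parameter file.

    Raises ``KeyError`` naming the first missing symbol and ``ValueError`` on
    sign/validation failures. Unknown keys are rejected to catch typos.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ValueError(f"{path}: expected a flat key: value map")
    return params_from_mapping(raw, allow_zero=allow_zero)


def params_from_mapping(raw: Mapping, allow_zero: Iterable[str] = ()) -> ModelParams:
    unknown = set(raw) - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
    for name in PARAM_NAMES:
        if name not in raw:
            raise KeyError(f"missing parameter {name}")
    p = ModelParams(**{k: _coerce(k, raw[k]) for k in PARAM_NAMES})
    p.validate(allow_zero=allow_zero)
    return p


def save_params(params: ModelParams, path: str | Path) -> None:
    """Write a flat YAML map; round-trips every numeric field bit-exactly
    (floats are serialised with repr precision)."""
    lines = []
    for name in PARAM_NAMES:
        v = getattr(params, name)
        lines.append(f"{name}: {int(v) if name in _INTEGER_FIELDS else repr(float(v))}")
    Path(path).write_text("\n".join(lines) + "\n")


def default_params() -> ModelParams:
    """The packaged default parameter set.

    This is a *synthetic* calibration (see the file header of
    ``_data/default_params_synthetic.yaml``): rate constants chosen to be
    biologically plausible for MSI-H/dMMR colorectal cancer, consistent with
    the printed baseline state (the checkpoint synthesis/decay and cytokine
    production/decay balances reproduce the tabulated initial concentrations)
    and with the timescale separation the QSSA reduction assumes.
    """
    ref = resources.files("pembrosim") / "_data" / "default_params_synthetic.yaml"
    with resources.as_file(ref) as path:
        return load_params(path)


# ---------------------------------------------------------------------------
# initial conditions
# ---------------------------------------------------------------------------

# Baseline (pre-treatment) state: tumour-site and TDLN cell densities,
# tumour-site cytokines, and unbound checkpoint concentrations. Drug and
# drug-bound complexes start at zero.
_DEFAULT_INIT: dict[str, float] = {
    # TS cells (cell/cm^3)
    "C": 1.79e7, "N_c": 1.99e6, "D_0": 1.63e6, "D": 8.29e5,
    "T_8": 2.43e5, "T_ex": 2.09e5, "T_r": 2.12e5,
    "M_0": 5.58e5, "M_2": 1.23e6, "K_0": 3.06e5, "K": 5.20e6,
    # TDLN cells (cell/cm^3)
    "D_LN": 1.05e7, "T0_8": 1.20e7, "TA_8": 1.30e6,
    "T0_r": 9.95e4, "TA_r": 7.85e5,
    # cytokines (g/cm^3)
    "I_2": 2.73e-12, "I_gamma": 1.83e-11, "I_alpha": 5.75e-11,
    "I_beta": 9.05e-7, "I_10": 6.22e-11, "I_12": 1.04e-12,
    # checkpoint species (molec/cm^3)
    "PD_T8": 6.70e8, "PD_K": 2.87e9, "P_L": 3.55e12,
    "PD_8LN": 1.56e9, "PL_LN": 1.86e11,
    # drug-bound complexes and drug (pre-treatment)
    "QA_T8": 0.0, "QA_K": 0.0, "QA_8LN": 0.0,
    "A_1": 0.0, "A1_LN": 0.0,
}

# Printed baseline PD-1/PD-L1 complex concentrations (molec/cm^3). These are
# algebraic in the model (bilinear QSSA closures), not dynamic states; they
# are kept for the cross-consistency checks in :mod:`pembrosim.verify`.
TABLE_TS_CHECKPOINT_INIT: dict[str, float] = {
    "PD_T8": 6.70e8, "PD_K": 2.87e9, "P_L": 3.55e12,
    "Q_T8": 5.06e5, "Q_K": 2.17e6,
}
TABLE_TDLN_CHECKPOINT_INIT: dict[str, float] = {
    "PD_8LN": 1.56e9, "PL_LN": 1.86e11, "Q_8LN": 6.18e4,
}


@dataclass(frozen=True)
class InitialState:
    """Initial value for every dynamic variable of the full model."""

    values: dict[str, float]

    @classmethod
    def default(cls) -> "InitialState":
        return cls(values=dict(_DEFAULT_INIT))

    @classmethod
    def from_mapping(cls, raw: Mapping) -> "InitialState":
        unknown = set(raw) - set(_DEFAULT_INIT)
        if unknown:
            raise ValueError(f"unknown state variable(s): {sorted(unknown)}")
        vals = dict(_DEFAULT_INIT)
        vals.update({k: float(v) for k, v in raw.items()})
        for k, v in vals.items():
            if v < 0:
                raise ValueError(f"initial {k} must be >= 0, got {v}")
        return cls(values=vals)

    @classmethod
    def load(cls, path: str | Path) -> "InitialState":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_mapping(raw)

    def replace(self, **changes: float) -> "InitialState":
        return InitialState.from_mapping({**self.values, **changes})

    def __getitem__(self, key: str) -> float:
        return self.values[key]


# ---------------------------------------------------------------------------
# dosing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseSchedule:
    """Intravenous bolus schedule: (time in days, dose in mg) pairs."""

    events: tuple[tuple[float, float], ...]

    def __post_init__(self):
        times = [t for t, _ in self.events]
        if any(t < 0 for t in times):
            raise ValueError("dose times must be >= 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("dose times must be strictly increasing")
        if any(xi < 0 for _, xi in self.events):
            raise ValueError("doses must be >= 0")

    @classmethod
    def empty(cls) -> "DoseSchedule":
        return cls(events=())

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(t for t, _ in self.events)

    @property
    def doses(self) -> tuple[float, ...]:
        return tuple(xi for _, xi in self.events)

    def __len__(self) -> int:
        return len(self.events)


def build_schedule(dose_mg: float, interval_days: float, n_doses: int) -> DoseSchedule:
    """Constant-dose regimen: ``n_doses`` infusions of ``dose_mg`` at times
    0, interval, ..., (n_doses - 1) * interval.

    The default neoadjuvant regimen is 200 mg every 21 days for 6 cycles.
    """
    if dose_mg < 0:
        raise ValueError("dose must be >= 0")
    if n_doses < 1:
        raise ValueError("need at least one dose")
    if n_doses > 1 and interval_days <= 0:
        raise ValueError("interval must be > 0 for repeated dosing")
    return DoseSchedule(
        events=tuple((j * interval_days, dose_mg) for j in range(n_doses))
    )


def dose_per_kg(dose_mg: float, patient_mass_kg: float) -> float:
    """Body-weight-normalised dose in mg/kg (200 mg / 80 kg = 2.5 mg/kg)."""
    if patient_mass_kg <= 0:
        raise ValueError("patient mass must be > 0")
    return dose_mg / patient_mass_kg
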