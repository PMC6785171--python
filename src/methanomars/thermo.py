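"""Gibbs energy of aerobic methane oxidation at arbitrary (T, P, composition).

The catabolic reaction is CH4 + 2 O2 -> CO2 + 2 H2O(l).  Standard formation
energies are corrected from the 298.15 K / 1 bar reference state to the
scenario temperature and pressure with the Helgeson formulation

    ΔfG°(T, P) = ΔfG°* − S°*(T − T*) + ∫ Cp° dT − T ∫ Cp° dlnT + ∫ V° dP,

where the heat capacity follows the empirical polynomial Cp°/R = A + BT − CT²
(closed-form integrals below) and the pressure integral is RT·ln(P/P*) for
gases (V° = RT/P) or V°·(P − P*) for liquid water (constant molal volume).
The in-situ Gibbs energy adds the fugacity quotient, with fugacities from the
van der Waals correction and the activity of liquid water taken as unity.

Temperatures are K, pressures atm internally (hPa accepted at the interface),
energies kJ mol⁻¹.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Mapping

import pandas as pd

from .constants import (
    HPA_PER_ATM,
    PA_PER_ATM,
    P_REF_ATM,
    R_KJ,
    R_L_ATM,
    STOICHIOMETRY,
    T_REF,
    hpa_to_atm,
)
from .exceptions import (
    ConfigurationError,
    SubstrateAbsentError,
    ThermodynamicDomainError,
)

logger = logging.getLogger(__name__)

REACTION_SPECIES = ("CO2", "O2", "CH4", "H2O")

#: Species that appear in the fugacity quotient (liquid water has activity 1).
QUOTIENT_SPECIES = ("CO2", "O2", "CH4")


@dataclass(frozen=True)
class SpeciesThermoRecord:
    """Standard-state thermodynamic and van der Waals constants of one species.

    Parameters
    ----------
    name : str
        Species identifier (e.g. ``"CO2"``).
    phase : str
        ``"gas"`` or ``"liquid"``.
    dfG_ref : float
        Standard molal Gibbs free energy of formation at 298.15 K, 1 bar
        (kJ mol⁻¹).
    S_ref : float
        Standard partial molal entropy at reference conditions
        (kJ mol⁻¹ K⁻¹).
    cp_A, cp_B, cp_C : float
        Coefficients of Cp°/R = A + B·T − C·T² (B in K⁻¹, C in K⁻²).
    vdw_a : float
        Van der Waals attraction constant (L² atm mol⁻²).
    vdw_b : float
        Van der Waals co-volume (L mol⁻¹).
    V_liquid : float
        Constant molal volume for the liquid phase (kJ Pa⁻¹ mol⁻¹); unused
        for gases.
    """

    name: str
    phase: str
    dfG_ref: float
    S_ref: float
    cp_A: float
    cp_B: float
    cp_C: float
    vdw_a: float = 0.0
    vdw_b: float = 0.0
    V_liquid: float = float("nan")

    def __post_init__(self) -> None:
        if self.phase not in ("gas", "liquid"):
            raise ConfigurationError(
                f"unknown phase {self.phase!r} for species {self.name!r}"
            )
        if not math.isfinite(self.dfG_ref):
            raise ConfigurationError(f"{self.name}: dfG_ref must be finite")
        if not self.S_ref > 0:
            raise ConfigurationError(f"{self.name}: S_ref must be positive")
        if self.vdw_a < 0 or self.vdw_b < 0:
            raise ConfigurationError(f"{self.name}: van der Waals constants must be >= 0")
        if self.phase == "liquid" and not self.V_liquid > 0:
            raise ConfigurationError(f"{self.name}: liquid phase requires V_liquid > 0")


@dataclass(frozen=True)
class AtmosphereState:
    """Temperature, total pressure and gas mixing ratios of a scenario.

    ``P_atm`` is the total pressure in atm; :meth:`from_hpa` accepts the
    hPa dialect used for martian surface pressures.  ``mix`` maps species
    names (case-insensitive) to volume mixing ratios γ_X (v/v).
    """

    T: float
    P_atm: float
    mix: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.T > 0:
            raise ThermodynamicDomainError(f"temperature must be positive, got {self.T}")
        if not self.P_atm > 0:
            raise ThermodynamicDomainError(f"pressure must be positive, got {self.P_atm}")
        norm = {str(k).upper(): float(v) for k, v in dict(self.mix).items()}
        for name, gamma in norm.items():
            if not 0.0 <= gamma <= 1.0:
                raise ThermodynamicDomainError(
                    f"mixing ratio of {name} must lie in [0, 1], got {gamma}"
                )
        if sum(norm.values()) > 1.0 + 1e-12:
            raise ThermodynamicDomainError("mixing ratios sum to more than 1")
        object.__setattr__(self, "mix", norm)

    @classmethod
    def from_hpa(cls, T: float, P_hPa: float, mix: Mapping[str, float]) -> "AtmosphereState":
        return cls(T=T, P_atm=hpa_to_atm(P_hPa), mix=mix)

    @property
    def P_hPa(self) -> float:
        return self.P_atm * HPA_PER_ATM

    def mixing_ratio(self, species: str) -> float:
        key = species.upper()
        if key not in self.mix:
            raise ConfigurationError(f"species {species!r} not present in atmosphere")
        return self.mix[key]

    def with_ch4(self, gamma_ch4: float) -> "AtmosphereState":
        """Return a copy with the CH4 mixing ratio replaced."""
        mix = dict(self.mix)
        mix["CH4"] = gamma_ch4
        return replace(self, mix=mix)


@dataclass(frozen=True)
class ReactionEnergy:
    """Standard and in-situ Gibbs energy change of CH4 oxidation.

    ``drG = drG_standard + R·T·Q_ln`` holds by construction; ``Q_ln`` is the
    natural log of the fugacity quotient f_CO2 / (f_O2² · f_CH4).
    """

    drG_standard: float
    drG: float
    Q_ln: float


def heat_capacity(record: SpeciesThermoRecord, T: float) -> float:
    """Standard molal isobaric heat capacity, kJ mol⁻¹ K⁻¹.

    Evaluates Cp° = R·(A + B·T − C·T²).
    """
    if not T > 0:
        raise ThermodynamicDomainError(f"temperature must be positive, got {T}")
    return R_KJ * (record.cp_A + record.cp_B * T - record.cp_C * T * T)


def _cp_integral(record: SpeciesThermoRecord, T: float) -> float:
    """∫_{T*}^{T} Cp° dT in closed form, kJ mol⁻¹."""
    A, B, C = record.cp_A, record.cp_B, record.cp_C
    return R_KJ * (
        A * (T - T_REF)
        + 0.5 * B * (T * T - T_REF * T_REF)
        - (C / 3.0) * (T**3 - T_REF**3)
    )


def _cp_dlnT_integral(record: SpeciesThermoRecord, T: float) -> float:
    """∫_{T*}^{T} Cp° dlnT in closed form, kJ mol⁻¹ K⁻¹."""
    A, B, C = record.cp_A, record.cp_B, record.cp_C
    return R_KJ * (
        A * math.log(T / T_REF)
        + B * (T - T_REF)
        - 0.5 * C * (T * T - T_REF * T_REF)
    )


def gibbs_formation_at_TP(record: SpeciesThermoRecord, T: float, P_atm: float) -> float:
    """Standard molal Gibbs free energy of formation at (T, P), kJ mol⁻¹.

    Corrects ``dfG_ref`` from the 298.15 K / 1 bar reference state using the
    entropy term, the closed-form heat-capacity integrals, and the pressure
    integral (RT·ln(P/P*) for gases, V°·(P − P*) for liquids).  At the
    reference state the result is ``dfG_ref`` exactly.
    """
    if not T > 0 or not P_atm > 0:
        raise ThermodynamicDomainError(
            f"temperature and pressure must be positive, got T={T}, P={P_atm}"
        )
    g = (
        record.dfG_ref
        - record.S_ref * (T - T_REF)
        + _cp_integral(record, T)
        - T * _cp_dlnT_integral(record, T)
    )
    if record.phase == "gas":
        g += R_KJ * T * math.log(P_atm / P_REF_ATM)
    elif record.phase == "liquid":
        if T < 273.15:
            logger.debug(
                "%s: liquid heat capacity extrapolated below freezing (T=%.2f K)",
                record.name,
                T,
            )
        g += record.V_liquid * (P_atm - P_REF_ATM) * PA_PER_ATM
    else:  # pragma: no cover - rejected at construction
        raise ConfigurationError(f"unknown phase {record.phase!r}")
    return g


def fugacity(record: SpeciesThermoRecord, atm: AtmosphereState) -> float:
    """Van der Waals fugacity of a gaseous species in the mixture, atm.

    f_X = γ_X·P_tot·exp{ (γ_X·P_tot / RT) · (b − a / RT) } with
    R = 0.08206 L atm K⁻¹ mol⁻¹.  Reduces to the partial pressure when the
    van der Waals constants vanish or the partial pressure goes to zero.
    """
    if record.phase != "gas":
        raise ThermodynamicDomainError(
            f"fugacity is defined for gases only; {record.name} is {record.phase}"
        )
    gamma = atm.mixing_ratio(record.name)
    partial = gamma * atm.P_atm
    if partial == 0.0:
        return 0.0
    rt = R_L_ATM * atm.T
    return partial * math.exp((partial / rt) * (record.vdw_b - record.vdw_a / rt))


def delta_rG_standard(
    records: Mapping[str, SpeciesThermoRecord], T: float, P_atm: float
) -> float:
    """Standard Gibbs energy change of CH4 + 2 O2 -> CO2 + 2 H2O at (T, P).

    kJ (mol CH4)⁻¹; stoichiometric combination of the per-species formation
    energies.
    """
    missing = [s for s in REACTION_SPECIES if s not in records]
    if missing:
        raise ConfigurationError(f"missing species records: {missing}")
    return sum(
        nu * gibbs_formation_at_TP(records[name], T, P_atm)
        for name, nu in STOICHIOMETRY.items()
    )


def delta_rG(
    records: Mapping[str, SpeciesThermoRecord], atm: AtmosphereState
) -> ReactionEnergy:
    """In-situ Gibbs energy change of aerobic CH4 oxidation.

    ΔrG = ΔrG° + RT·[ln f_CO2 − 2 ln f_O2 − ln f_CH4]; liquid water enters
    with unit activity.  Raises :class:`SubstrateAbsentError` when CH4 or O2
    is absent (the logarithm diverges).
    """
    for substrate in ("CH4", "O2"):
        if atm.mixing_ratio(substrate) == 0.0:
            raise SubstrateAbsentError(f"substrate absent: {substrate}")
    if atm.mixing_ratio("CO2") == 0.0:
        raise ThermodynamicDomainError("CO2 mixing ratio of zero makes ln Q diverge")
    q_ln = (
        math.log(fugacity(records["CO2"], atm))
        - 2.0 * math.log(fugacity(records["O2"], atm))
        - math.log(fugacity(records["CH4"], atm))
    )
    g0 = delta_rG_standard(records, atm.T, atm.P_atm)
    return ReactionEnergy(drG_standard=g0, drG=g0 + R_KJ * atm.T * q_ln, Q_ln=q_ln)


_TABLE_COLUMNS = {
    "name": "name",
    "phase": "phase",
    "dfG_ref_kJ_mol": "dfG_ref",
    "S_ref_kJ_mol_K": "S_ref",
    "cp_A": "cp_A",
    "cp_B": "cp_B",
    "cp_C": "cp_C",
    "vdw_a_L2atm_mol2": "vdw_a",
    "vdw_b_L_mol": "vdw_b",
}


def load_species_table(path: str | Path | None = None) -> dict[str, SpeciesThermoRecord]:
    """Read a species-constant CSV into a name-keyed record mapping.

    When ``path`` is None the table shipped with the package (CO2, O2, CH4,
    H2O) is used.  The optional trailing column ``V_liquid_kJ_Pa_mol`` holds
    the constant molal volume of liquid species.
    """
    if path is None:
        path = Path(__file__).parent / "data" / "species_thermo.csv"
    df = pd.read_csv(path)
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"species table missing columns: {sorted(missing)}")
    records: dict[str, SpeciesThermoRecord] = {}
    for _, row in df.iterrows():
        kwargs = {attr: row[col] for col, attr in _TABLE_COLUMNS.items()}
        v_liq = row.get("V_liquid_kJ_Pa_mol", float("nan"))
        if pd.notna(v_liq):
            kwargs["V_liquid"] = float(v_liq)
        kwargs["name"] = str(kwargs["name"])
        kwargs["phase"] = str(kwargs["phase"])
        rec = SpeciesThermoRecord(**kwargs)
        records[rec.name] = rec
    return records


@lru_cache(maxsize=1)
def default_species_table() -> dict[str, SpeciesThermoRecord]:
    """Cached copy of the shipped species table."""
    return load_species_table(None)
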