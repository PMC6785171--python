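"""Cell-specific CH4 oxidation kinetics.

Dual-substrate Michaelis–Menten rate law,

    r = v_max · [CH4]/(K_CH4 + [CH4]) · [O2]/(K_O2 + [O2]),

with gas-phase molar concentrations from the ideal-gas relation
[X] = γ_X·P_tot/(R·T), R = 0.08206 L atm K⁻¹ mol⁻¹.  Rates are per cell and
per hour throughout the package.  The soil-gas mixing ratio is assumed equal
to the atmospheric one; callers may override the CH4 mixing ratio via
:meth:`AtmosphereState.with_ch4`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .constants import R_L_ATM
from .exceptions import ConfigurationError, ThermodynamicDomainError
from .thermo import AtmosphereState

#: Only reported O2 half-saturation constant (Methylocystis sp. MOX-1),
#: mol L⁻¹; applied to every strain unless the strain table states otherwise.
DEFAULT_K_O2 = 1.9e-9

STRAIN_TABLE_COLUMNS = ("strain_id", "vmax_mol_cell_h", "K_ch4_mol_L", "K_o2_mol_L")


@dataclass(frozen=True)
class StrainKinetics:
    """Michaelis–Menten parameters of one methanotroph strain.

    v_max in mol CH4 cell⁻¹ h⁻¹; K_CH4 and K_O2 in mol L⁻¹.
    """

    strain_id: str
    v_max: float
    K_CH4: float
    K_O2: float = DEFAULT_K_O2

    def __post_init__(self) -> None:
        if not self.v_max > 0:
            raise ConfigurationError(f"{self.strain_id}: v_max must be positive")
        if not self.K_CH4 > 0 or not self.K_O2 > 0:
            raise ConfigurationError(
                f"{self.strain_id}: half-saturation constants must be positive"
            )


def gas_molar_concentration(atm: AtmosphereState, species: str) -> float:
    """Molar concentration of a gas in the mixture, mol L⁻¹.

    [X] = γ_X·P_tot / (R·T).
    """
    gamma = atm.mixing_ratio(species)
    return gamma * atm.P_atm / (R_L_ATM * atm.T)


def oxidation_rate(strain: StrainKinetics, ch4_conc: float, o2_conc: float) -> float:
    """Cell-specific CH4 oxidation rate, mol CH4 cell⁻¹ h⁻¹."""
    if ch4_conc < 0 or o2_conc < 0:
        raise ThermodynamicDomainError("concentrations must be non-negative")
    return (
        strain.v_max
        * ch4_conc
        / (strain.K_CH4 + ch4_conc)
        * o2_conc
        / (strain.K_O2 + o2_conc)
    )


def oxidation_rate_at(strain: StrainKinetics, atm: AtmosphereState) -> float:
    """Oxidation rate at the concentrations implied by an atmosphere state."""
    return oxidation_rate(
        strain,
        gas_molar_concentration(atm, "CH4"),
        gas_molar_concentration(atm, "O2"),
    )


def read_strain_table(path: str | Path) -> list[StrainKinetics]:
    """Read a strain-kinetics CSV.

    Expected header: ``strain_id,vmax_mol_cell_h,K_ch4_mol_L,K_o2_mol_L``;
    empty ``K_o2_mol_L`` cells default to 1.9×10⁻⁹ mol L⁻¹.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(STRAIN_TABLE_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ConfigurationError(f"strain table missing columns: {sorted(missing)}")
    strains = []
    for _, row in df.iterrows():
        k_o2 = row.get("K_o2_mol_L", math.nan)
        strains.append(
            StrainKinetics(
                strain_id=str(row["strain_id"]),
                v_max=float(row["vmax_mol_cell_h"]),
                K_CH4=float(row["K_ch4_mol_L"]),
                K_O2=DEFAULT_K_O2 if pd.isna(k_o2) else float(k_o2),
            )
        )
    return strains


def write_strain_table(strains: Iterable[StrainKinetics], path: str | Path) -> None:
    """Write strains to the CSV dialect accepted by :func:`read_strain_table`."""
    df = strains_to_frame(strains)
    df.to_csv(path, index=False)


def strains_to_frame(strains: Iterable[StrainKinetics]) -> pd.DataFrame:
    rows = [
        {
            "strain_id": s.strain_id,
            "vmax_mol_cell_h": s.v_max,
            "K_ch4_mol_L": s.K_CH4,
            "K_o2_mol_L": s.K_O2,
        }
        for s in strains
    ]
    return pd.DataFrame(rows, columns=list(STRAIN_TABLE_COLUMNS))
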