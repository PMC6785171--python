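"""Maintenance-energy budgets, survival thresholds and doubling times.

This module combines the thermodynamic driving force (``thermo``) with the
cell-specific oxidation kinetics (``kinetics``) into the quantities that
decide viability:

* power supply            −r·ΔrG                      (kJ cell⁻¹ h⁻¹)
* maintenance demand      m_E = p·exp(A − B/T)        (kJ cell⁻¹ h⁻¹)
* net energy gain         −r·ΔrG − m_E                (kJ cell⁻¹ h⁻¹)
* doubling time           Y·ln2 / net gain            (Earth years)
* minimum CH4 threshold   mixing ratio where net gain = 0

The Arrhenius maintenance law is calibrated on sub-zero maintenance-rate
observations for psychrophilic and psychrotolerant organisms; the per-cell
prefactor 10⁻¹⁵ is the mol-C content of one cell (12 fg-C / 12.01 g mol⁻¹).
``MaintenanceArrheniusModel`` exposes that calibration as a fit/results pair
with parameter uncertainties and a pointwise 95% confidence band.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .constants import (
    AVOGADRO,
    CARBON_MOLAR_MASS,
    CM2_PER_M2,
    G_PER_FG,
    HOURS_PER_EARTH_YEAR,
    R_KJ,
    R_L_ATM,
    SECONDS_PER_HOUR,
)
from .exceptions import ConfigurationError, FitError, ThermodynamicDomainError
from .kinetics import StrainKinetics, gas_molar_concentration, oxidation_rate
from .thermo import (
    AtmosphereState,
    SpeciesThermoRecord,
    default_species_table,
    delta_rG,
)

logger = logging.getLogger(__name__)

#: Gibbs energy needed to synthesise 1 gC of autotrophic nitrifier biomass.
NITRIFIER_SYNTHESIS_KJ_PER_GC = 291.4


# ---------------------------------------------------------------------------
# maintenance law
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaintenanceModel:
    """Arrhenius maintenance-energy law m_E(T) = prefactor·exp(A − B/T).

    ``prefactor`` converts from per-mol-C to per-cell (default 10⁻¹⁵ mol C
    cell⁻¹, i.e. 12 fg-C cell⁻¹ / 12.01 g mol⁻¹); ``arrh_A`` is the
    dimensionless intercept and ``arrh_B`` the slope in K.  The default
    coefficients are the sub-10 °C calibration used throughout the analysis.
    """

    prefactor: float = 1e-15
    arrh_A: float = 144.9
    arrh_B: float = 39656.0

    def __post_init__(self) -> None:
        if not self.prefactor > 0:
            raise ConfigurationError("prefactor must be positive")
        if not self.arrh_B > 0:
            raise ConfigurationError("arrh_B must be positive")

    def rate(self, T: float) -> float:
        return maintenance_rate(self, T)


def maintenance_rate(model: MaintenanceModel, T: float) -> float:
    """Cell-specific maintenance energy requirement rate, kJ cell⁻¹ h⁻¹."""
    if not T > 0:
        raise ThermodynamicDomainError(f"temperature must be positive, got {T}")
    return model.prefactor * math.exp(model.arrh_A - model.arrh_B / T)


# ---------------------------------------------------------------------------
# biomass synthesis energy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiomassEnergyParams:
    """Inputs to the Heijnen dissipation correlation for one carbon source.

    ``carbon_atoms`` and ``degree_of_reduction`` describe the carbon source
    (CH4: C = 1, γ = 8); ``cell_carbon`` is the cellular carbon content in
    fg-C cell⁻¹.
    """

    carbon_atoms: int = 1
    degree_of_reduction: float = 8.0
    cell_carbon: float = 12.0

    def __post_init__(self) -> None:
        if self.carbon_atoms < 1:
            raise ConfigurationError("carbon_atoms must be >= 1")
        if not 0 < self.degree_of_reduction <= 8:
            raise ConfigurationError("degree_of_reduction must lie in (0, 8]")
        if not self.cell_carbon > 0:
            raise ConfigurationError("cell_carbon must be positive")


def dissipation_energy_per_molC(carbon_atoms: int, degree_of_reduction: float) -> float:
    """Heijnen dissipation energy of biomass synthesis, kJ (mol C)⁻¹.

    200 + 18·(6 − C)^1.8 + exp[|3.8 − γ|^0.32 · (3.6 + 0.4·C)].
    """
    c = carbon_atoms
    g = degree_of_reduction
    return 200.0 + 18.0 * (6.0 - c) ** 1.8 + math.exp(
        abs(3.8 - g) ** 0.32 * (3.6 + 0.4 * c)
    )


def synthesis_energy_per_gC(carbon_atoms: int, degree_of_reduction: float) -> float:
    """Gibbs energy to synthesise 1 gC of biomass, kJ gC⁻¹."""
    return dissipation_energy_per_molC(carbon_atoms, degree_of_reduction) / CARBON_MOLAR_MASS


def biomass_synthesis_energy(params: BiomassEnergyParams) -> float:
    """Gibbs energy Y required to synthesise one cell, kJ cell⁻¹.

    Per-gC synthesis energy for the given carbon source times the cellular
    carbon content (fg-C converted to g).  Linear in ``cell_carbon``.
    """
    per_gc = synthesis_energy_per_gC(params.carbon_atoms, params.degree_of_reduction)
    return per_gc * params.cell_carbon * G_PER_FG


#: Energy cost of one methanotroph cell grown on CH4 (C=1, γ=8, 12 fg-C).
DEFAULT_CELL_SYNTHESIS_KJ = biomass_synthesis_energy(BiomassEnergyParams())


# ---------------------------------------------------------------------------
# energy budget
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnergyBudget:
    """Per-strain, per-scenario energy bookkeeping.

    ``doubling_time_yr`` is ``math.inf`` whenever the net gain is
    non-positive; the identities ``power_supply = −rate_r·drG`` and
    ``net_gain = power_supply − maintenance`` hold to machine precision.
    """

    strain_id: str
    T: float
    P_hPa: float
    ch4_ppbv: float
    rate_r: float
    drG: float
    power_supply: float
    maintenance: float
    net_gain: float
    doubling_time_yr: float


def doubling_time_years(Y: float, net_gain: float) -> float:
    """Cell doubling time Y·ln2 / net gain, converted to Earth years.

    Infinite when the net energy gain rate is non-positive (the cell cannot
    cover maintenance, let alone divide).
    """
    if net_gain <= 0:
        return math.inf
    return Y * math.log(2.0) / net_gain / HOURS_PER_EARTH_YEAR


def energy_budget(
    strain: StrainKinetics,
    atm: AtmosphereState,
    model: MaintenanceModel | None = None,
    Y: float | None = None,
    species: Mapping[str, SpeciesThermoRecord] | None = None,
    efficiency: float = 1.0,
) -> EnergyBudget:
    """Full energy budget of one strain in one environmental scenario.

    ``efficiency`` scales the catabolic power actually captured by the cell
    (default 1: no heat-dissipation discount, so the doubling time is a
    minimum estimate).
    """
    model = model or MaintenanceModel()
    species = species or default_species_table()
    if Y is None:
        Y = DEFAULT_CELL_SYNTHESIS_KJ
    rxn = delta_rG(species, atm)
    r = oxidation_rate(
        strain,
        gas_molar_concentration(atm, "CH4"),
        gas_molar_concentration(atm, "O2"),
    )
    power = -r * rxn.drG * efficiency
    m_e = maintenance_rate(model, atm.T)
    net = power - m_e
    return EnergyBudget(
        strain_id=strain.strain_id,
        T=atm.T,
        P_hPa=atm.P_hPa,
        ch4_ppbv=atm.mixing_ratio("CH4") / 1e-9,
        rate_r=r,
        drG=rxn.drG,
        power_supply=power,
        maintenance=m_e,
        net_gain=net,
        doubling_time_yr=doubling_time_years(Y, net),
    )


# ---------------------------------------------------------------------------
# minimum CH4 threshold
# ---------------------------------------------------------------------------

def minimum_ch4_threshold(
    strain: StrainKinetics,
    atm_template: AtmosphereState,
    model: MaintenanceModel | None = None,
    species: Mapping[str, SpeciesThermoRecord] | None = None,
    rel_tol: float = 1e-8,
    max_iter: int = 50,
) -> float:
    """Minimum CH4 mixing ratio for survival, in ppbv.

    Solves net gain = 0 for the CH4 mixing ratio.  At fixed ΔrG the
    Michaelis–Menten balance has the closed form

        [CH4]* = θ·K_CH4 / (1 − θ),   θ = m_E / (v_max·g_O2·(−ΔrG)),

    where g_O2 is the O2 saturation factor.  Because ΔrG depends only
    logarithmically on the CH4 mixing ratio, the closed form is iterated as a
    fixed point, recomputing ΔrG at each candidate mixing ratio, until the
    relative change falls below ``rel_tol``.

    Returns ``math.inf`` when even saturating CH4 cannot cover maintenance
    (θ ≥ 1: not viable at any CH4 level) or when the root exceeds the
    mixing-ratio headroom left by the other gases; raises on failure to
    converge so numeric trouble is never mistaken for non-viability.  When
    maintenance is negligible the kinetic root collapses onto the
    thermodynamic equilibrium CH4 level (where ΔrG = 0), which bounds the
    threshold from below and is returned in that regime.
    """
    model = model or MaintenanceModel()
    species = species or default_species_table()
    m_e = maintenance_rate(model, atm_template.T)
    if m_e == 0.0:
        return 0.0
    o2_conc = gas_molar_concentration(atm_template, "O2")
    g_o2 = o2_conc / (strain.K_O2 + o2_conc)
    if g_o2 == 0.0:
        raise ThermodynamicDomainError("O2 absent: no finite CH4 threshold exists")

    # CH4 cannot exceed the mixing-ratio headroom left by the other gases
    headroom = 1.0 - sum(
        g for name, g in atm_template.mix.items() if name != "CH4"
    )
    gamma = atm_template.mixing_ratio("CH4") or 0.69e-9  # starting guess
    rt_over_p = R_L_ATM * atm_template.T / atm_template.P_atm
    for _ in range(max_iter):
        rxn = delta_rG(species, atm_template.with_ch4(gamma))
        # drG is linear in ln(gamma_CH4) with slope -RT, so the equilibrium
        # mixing ratio (drG = 0) follows in closed form from any evaluation
        gamma_eq = gamma * math.exp(rxn.drG / (R_KJ * atm_template.T))
        if rxn.drG >= 0:
            # current iterate sits below equilibrium; restart just above it
            gamma = 2.0 * gamma_eq
            continue
        theta = m_e / (strain.v_max * g_o2 * (-rxn.drG))
        if theta >= 1.0:
            logger.debug(
                "%s: maintenance exceeds saturating power supply (theta=%.3g)",
                strain.strain_id,
                theta,
            )
            return math.inf
        ch4_star = theta * strain.K_CH4 / (1.0 - theta)
        gamma_new = ch4_star * rt_over_p
        if gamma_new <= gamma_eq:
            # maintenance so small that the kinetic root sits at (or below)
            # the thermodynamic equilibrium CH4 level, which pins it
            return gamma_eq / 1e-9
        if gamma_new > headroom:
            logger.debug(
                "%s: threshold mixing ratio %.3g exceeds atmospheric headroom %.3g",
                strain.strain_id,
                gamma_new,
                headroom,
            )
            return math.inf
        if abs(gamma_new - gamma) <= rel_tol * gamma_new:
            return gamma_new / 1e-9
        gamma = gamma_new
    raise ThermodynamicDomainError(
        f"{strain.strain_id}: threshold fixed point did not converge in {max_iter} iterations"
    )


# ---------------------------------------------------------------------------
# areal population budget
# ---------------------------------------------------------------------------

def net_ch4_sink(production_flux: float, photochemical_loss: float) -> float:
    """Net CH4 flux available to microbial consumption, molecules cm⁻² s⁻¹."""
    if photochemical_loss > production_flux:
        raise ThermodynamicDomainError(
            "photochemical loss exceeds production; no microbial sink remains"
        )
    return production_flux - photochemical_loss


def areal_cell_density(
    strain: StrainKinetics,
    atm: AtmosphereState,
    consumption_flux: float,
    per_hour: bool = True,
) -> float:
    """Cell density sustaining a CH4 consumption flux, cells cm⁻².

    The flux (molecules cm⁻² s⁻¹) is converted to mol cm⁻² h⁻¹ via the
    Avogadro constant and 3600 s h⁻¹, then divided by the cell-specific
    oxidation rate r (mol cell⁻¹ h⁻¹).  ``per_hour=False`` instead divides
    the per-second molar flux directly by the per-hour rate — a dimensionally
    inconsistent convention retained for comparison with published ensemble
    figures, and logged as such.
    """
    if consumption_flux < 0:
        raise ThermodynamicDomainError("consumption flux must be non-negative")
    r = oxidation_rate(
        strain,
        gas_molar_concentration(atm, "CH4"),
        gas_molar_concentration(atm, "O2"),
    )
    if r == 0.0:
        raise ThermodynamicDomainError(
            f"{strain.strain_id}: oxidation rate is zero; areal density undefined"
        )
    mol_flux_per_s = consumption_flux / AVOGADRO
    if per_hour:
        return mol_flux_per_s * SECONDS_PER_HOUR / r
    logger.debug(
        "%s: using per-second flux over per-hour rate (published convention)",
        strain.strain_id,
    )
    return mol_flux_per_s / r


def areal_biomass(density: float, cell_carbon: float = 12.0) -> float:
    """Methanotrophic biomass per unit surface area, gC m⁻².

    ``density`` in cells cm⁻², ``cell_carbon`` in fg-C cell⁻¹.
    """
    if density < 0 or cell_carbon < 0:
        raise ThermodynamicDomainError("inputs must be non-negative")
    return density * cell_carbon * G_PER_FG * CM2_PER_M2


# ---------------------------------------------------------------------------
# maintenance observations and the Arrhenius fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaintenanceObservation:
    """One literature maintenance-rate observation.

    ``value`` is in ``source_units``: either specific carbon turnover
    (gC (gC)⁻¹ h⁻¹) or energy per mol biomass carbon (kJ (mol C)⁻¹ h⁻¹).
    """

    T: float
    value: float
    source_units: str = "kJ_per_molC_h"
    organism_class: str = "other"

    def __post_init__(self) -> None:
        if not self.T > 0:
            raise ConfigurationError("T must be positive")
        if not self.value > 0:
            raise ConfigurationError("value must be positive")
        if self.source_units not in ("gC_per_gC_h", "kJ_per_molC_h"):
            raise ConfigurationError(f"unknown source units {self.source_units!r}")


def convert_maintenance_units(
    obs: MaintenanceObservation,
    biomass_energy_per_gC: float | None = None,
) -> float:
    """Convert an observation to kJ (mol C)⁻¹ h⁻¹.

    Carbon-turnover observations are scaled by the Gibbs energy needed to
    synthesise 1 gC of the organism's biomass (291.4 kJ gC⁻¹ for autotrophic
    nitrifiers; for heterotrophs the Heijnen value for their carbon source,
    supplied by the caller) times 12.01 gC (mol C)⁻¹.  Observations already
    in energy units pass through unchanged.
    """
    if obs.source_units == "kJ_per_molC_h":
        return obs.value
    if obs.source_units == "gC_per_gC_h":
        if biomass_energy_per_gC is None:
            if obs.organism_class == "nitrifier":
                biomass_energy_per_gC = NITRIFIER_SYNTHESIS_KJ_PER_GC
            else:
                raise ConfigurationError(
                    "biomass_energy_per_gC required for non-nitrifier carbon-turnover data"
                )
        return obs.value * biomass_energy_per_gC * CARBON_MOLAR_MASS
    raise ConfigurationError(f"unknown source units {obs.source_units!r}")


class MaintenanceArrheniusModel:
    """OLS calibration of ln m_E against inverse temperature.

    The model is ln m = A − B/T with m in kJ (mol C)⁻¹ h⁻¹.  Observations
    warmer than ``T_max`` (default 283.15 K: the correlation is meant for
    cold-adapted metabolism) are excluded before fitting.
    """

    def __init__(
        self,
        temperatures: Sequence[float],
        values: Sequence[float],
        T_max: float = 283.15,
    ) -> None:
        T = np.asarray(temperatures, dtype=float)
        m = np.asarray(values, dtype=float)
        if T.shape != m.shape:
            raise FitError("temperatures and values must have equal length")
        keep = T <= T_max
        self.T = T[keep]
        self.values = m[keep]
        self.T_max = T_max
        if self.T.size < 3:
            raise FitError(
                f"need at least 3 observations at T <= {T_max} K, got {self.T.size}"
            )
        if np.any(self.values <= 0) or np.any(self.T <= 0):
            raise FitError("observations must be positive")

    @classmethod
    def from_observations(
        cls,
        observations: Iterable[MaintenanceObservation],
        T_max: float = 283.15,
    ) -> "MaintenanceArrheniusModel":
        obs = list(observations)
        if not obs:
            raise FitError("no observations supplied")
        return cls(
            [o.T for o in obs],
            [convert_maintenance_units(o) for o in obs],
            T_max=T_max,
        )

    def fit(self) -> "MaintenanceArrheniusResults":
        import statsmodels.api as sm

        x = 1.0 / self.T
        y = np.log(self.values)
        exog = sm.add_constant(x)
        res = sm.OLS(y, exog).fit()
        return MaintenanceArrheniusResults(self, res)


class MaintenanceArrheniusResults:
    """Fitted Arrhenius maintenance law with OLS uncertainties.

    ``arrh_A`` is the intercept of ln m on 1/T and ``arrh_B`` the (positive)
    slope magnitude in K.  ``confidence_band`` returns the standard pointwise
    OLS band of the regression line, mapped back to rate units.
    """

    def __init__(self, model: MaintenanceArrheniusModel, ols_results) -> None:
        self.model = model
        self._res = ols_results
        self.arrh_A = float(ols_results.params[0])
        self.arrh_B = float(-ols_results.params[1])

    @property
    def params(self) -> tuple[float, float]:
        return (self.arrh_A, self.arrh_B)

    def conf_int(self, alpha: float = 0.05) -> dict[str, tuple[float, float]]:
        """Confidence intervals for (arrh_A, arrh_B)."""
        ci = np.asarray(self._res.conf_int(alpha=alpha))
        a_lo, a_hi = ci[0]
        s_lo, s_hi = ci[1]
        # slope of the regression is −B: negate and swap the bounds
        return {"arrh_A": (a_lo, a_hi), "arrh_B": (-s_hi, -s_lo)}

    def predict(self, T) -> np.ndarray:
        """Fitted maintenance rate in kJ (mol C)⁻¹ h⁻¹ at temperatures T."""
        T = np.asarray(T, dtype=float)
        return np.exp(self.arrh_A - self.arrh_B / T)

    def confidence_band(self, T, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise OLS confidence band on the fitted line, in rate units."""
        import statsmodels.api as sm

        T = np.atleast_1d(np.asarray(T, dtype=float))
        exog = sm.add_constant(1.0 / T, has_constant="add")
        pred = self._res.get_prediction(exog)
        ci = pred.conf_int(alpha=alpha)
        return np.exp(ci[:, 0]), np.exp(ci[:, 1])

    def maintenance_model(self, prefactor: float = 1e-15) -> MaintenanceModel:
        """Per-cell maintenance law; prefactor = mol C per cell."""
        return MaintenanceModel(
            prefactor=prefactor, arrh_A=self.arrh_A, arrh_B=self.arrh_B
        )

    def summary(self) -> str:
        head = (
            "Arrhenius maintenance-energy fit: ln m = A - B/T "
            f"(n={self.model.T.size}, T <= {self.model.T_max:.2f} K)\n"
            f"A = {self.arrh_A:.4f}, B = {self.arrh_B:.1f} K\n"
        )
        return head + str(self._res.summary())


def fit_arrhenius_maintenance(
    observations: Iterable[MaintenanceObservation],
    T_max: float = 283.15,
) -> MaintenanceArrheniusResults:
    """Convenience wrapper: build the model from observations and fit it."""
    return MaintenanceArrheniusModel.from_observations(observations, T_max=T_max).fit()
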