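"""Synthetic strain ensembles, maintenance datasets and scenario grids.

The published kinetic compilation behind the 19-strain ensemble is not
redistributable, so ensembles are drawn log-uniformly within the printed
parameter ranges (v_max spans two orders of magnitude, so a scale-free
distribution is the natural neutral choice); the one strain whose parameters
are printed in full, Methylocystis sp. LR1, ships as a fixture.  Synthetic
maintenance datasets place multiplicative lognormal noise on the Arrhenius
mean, which is the error structure the log-linear fit assumes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bioenergetics import MaintenanceModel, MaintenanceObservation
from .exceptions import ConfigurationError
from .kinetics import DEFAULT_K_O2, StrainKinetics
from .thermo import AtmosphereState

logger = logging.getLogger(__name__)

#: Printed v_max range of the 19-strain compilation, mol CH4 cell⁻¹ h⁻¹.
VMAX_RANGE = (5.6e-18, 5.7e-16)

#: Printed K_CH4 range of the 19-strain compilation, mol L⁻¹.
KCH4_RANGE = (1.0e-6, 2.3e-5)

#: Martian surface grid bounds used throughout: T in K, P in hPa.
MARS_T_RANGE = (180.0, 280.0)
MARS_P_RANGE = (6.0, 11.0)

#: Default martian near-surface mixing ratios (v/v).
MARS_MIX = {"CO2": 0.95, "O2": 0.00145, "CH4": 0.69e-9}

#: Earth reference atmosphere for rate comparisons (CH4 1.8 ppmv).
EARTH_MIX = {"CO2": 410e-6, "O2": 0.2095, "CH4": 1.8e-6}


@dataclass(frozen=True)
class StrainEnsembleSpec:
    """Sampling specification for a synthetic strain ensemble.

    ``correlation`` is the rank correlation between log v_max and log K_CH4
    (0 by default: no information about their joint distribution exists).
    """

    n_strains: int = 19
    vmax_range: tuple[float, float] = VMAX_RANGE
    kch4_range: tuple[float, float] = KCH4_RANGE
    k_o2: float = DEFAULT_K_O2
    seed: int = 0
    correlation: float = 0.0

    def __post_init__(self) -> None:
        if self.n_strains < 1:
            raise ConfigurationError("n_strains must be >= 1")
        for lo, hi in (self.vmax_range, self.kch4_range):
            if not (0 < lo < hi):
                raise ConfigurationError("parameter ranges must be positive and ordered")
        if not self.k_o2 > 0:
            raise ConfigurationError("k_o2 must be positive")
        if not -1.0 <= self.correlation <= 1.0:
            raise ConfigurationError("correlation must lie in [-1, 1]")


def sample_strain_ensemble(spec: StrainEnsembleSpec) -> list[StrainKinetics]:
    """Draw a reproducible ensemble of strain kinetics.

    v_max and K_CH4 are log-uniform within the printed ranges; a non-zero
    ``correlation`` couples them through a Gaussian copula on the log scale.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_strains
    if spec.correlation == 0.0:
        u_v = rng.uniform(size=n)
        u_k = rng.uniform(size=n)
    else:
        from scipy.stats import norm

        cov = [[1.0, spec.correlation], [spec.correlation, 1.0]]
        z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
        u_v, u_k = norm.cdf(z[:, 0]), norm.cdf(z[:, 1])
    lo_v, hi_v = np.log(spec.vmax_range)
    lo_k, hi_k = np.log(spec.kch4_range)
    vmax = np.exp(lo_v + u_v * (hi_v - lo_v))
    kch4 = np.exp(lo_k + u_k * (hi_k - lo_k))
    return [
        StrainKinetics(
            strain_id=f"synthetic_{i:03d}",
            v_max=float(vmax[i]),
            K_CH4=float(kch4[i]),
            K_O2=spec.k_o2,
        )
        for i in range(n)
    ]


def lr1_fixture() -> StrainKinetics:
    """Methylocystis sp. LR1 with its printed kinetic parameters."""
    return StrainKinetics(
        strain_id="Methylocystis_sp_LR1",
        v_max=5e-17,
        K_CH4=2.5e-6,
        K_O2=DEFAULT_K_O2,
    )


def synth_maintenance_dataset(
    model: MaintenanceModel,
    T_points: Sequence[float],
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> list[MaintenanceObservation]:
    """Synthetic sub-zero maintenance observations, kJ (mol C)⁻¹ h⁻¹.

    Values are the Arrhenius mean (per mol C, i.e. the per-cell law divided
    by its prefactor) times lognormal multiplicative noise of log-scale
    ``noise_sigma``.
    """
    T_points = list(T_points)
    if not T_points:
        raise ConfigurationError("T_points must not be empty")
    for T in T_points:
        if not 180.0 < T <= 283.15:
            raise ConfigurationError(
                f"T_points must lie in (180, 283.15] K, got {T}"
            )
    rng = np.random.default_rng(seed)
    obs = []
    for T in T_points:
        mean = math.exp(model.arrh_A - model.arrh_B / T)
        noise = math.exp(rng.normal(0.0, noise_sigma)) if noise_sigma > 0 else 1.0
        obs.append(
            MaintenanceObservation(
                T=float(T),
                value=mean * noise,
                source_units="kJ_per_molC_h",
                organism_class="other",
            )
        )
    return obs


def mars_default_atmosphere(T: float = 230.0, P_hPa: float = 6.0) -> AtmosphereState:
    """Martian near-surface atmosphere: 95% CO2, 0.145% O2, 0.69 ppbv CH4."""
    if not (MARS_T_RANGE[0] <= T <= MARS_T_RANGE[1]):
        logger.warning("temperature %.1f K outside the martian surface grid", T)
    if not (MARS_P_RANGE[0] <= P_hPa <= MARS_P_RANGE[1]):
        logger.warning("pressure %.2f hPa outside the martian surface grid", P_hPa)
    return AtmosphereState.from_hpa(T, P_hPa, MARS_MIX)


def earth_reference_atmosphere(T: float = 298.15, P_hPa: float = 1013.25) -> AtmosphereState:
    """Earth reference atmosphere (CH4 1.8 ppmv) for rate-scale comparisons."""
    return AtmosphereState.from_hpa(T, P_hPa, EARTH_MIX)


@dataclass(frozen=True)
class EnvironmentGridSpec:
    """Rectangular (T, P) scenario grid with fixed martian mixing ratios."""

    T_range: tuple[float, float] = MARS_T_RANGE
    P_range: tuple[float, float] = MARS_P_RANGE
    resolution: int = 51
    mix: dict[str, float] = field(default_factory=lambda: dict(MARS_MIX))

    def __post_init__(self) -> None:
        if self.resolution < 2:
            raise ConfigurationError("grid resolution must be >= 2")
        for lo, hi in (self.T_range, self.P_range):
            if not (0 < lo <= hi):
                raise ConfigurationError("grid ranges must be positive and ordered")

    def temperatures(self) -> np.ndarray:
        lo, hi = self.T_range
        if lo == hi:  # degenerate axis: a single scenario temperature
            return np.array([lo])
        return np.linspace(lo, hi, self.resolution)

    def pressures_hpa(self) -> np.ndarray:
        lo, hi = self.P_range
        if lo == hi:
            return np.array([lo])
        return np.linspace(lo, hi, self.resolution)

    def atmospheres(self):
        """Yield an AtmosphereState per grid node (T outer, P inner)."""
        for T in self.temperatures():
            for P in self.pressures_hpa():
                yield AtmosphereState.from_hpa(float(T), float(P), self.mix)
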