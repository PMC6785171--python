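"""Run orchestration: energy maps, viability tables and the CH4 budget.

Each run writes RFC 4180 CSV tables prefixed with a single ``#``-comment
provenance line (a JSON echo of the configuration, the seed and the package
version — no timestamps, so re-running an identical configuration produces
byte-identical files).  Plots are optional conveniences; every result the
package stands behind is in the tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .bioenergetics import (
    BiomassEnergyParams,
    MaintenanceModel,
    areal_biomass,
    areal_cell_density,
    biomass_synthesis_energy,
    energy_budget,
    minimum_ch4_threshold,
    net_ch4_sink,
)
from .constants import AVOGADRO, SECONDS_PER_HOUR
from .exceptions import ConfigurationError, MethanomarsError
from .kinetics import StrainKinetics, read_strain_table
from .synth import (
    EnvironmentGridSpec,
    StrainEnsembleSpec,
    lr1_fixture,
    sample_strain_ensemble,
)
from .thermo import AtmosphereState, default_species_table, delta_rG

logger = logging.getLogger(__name__)

VIABILITY_COLUMNS = [
    "strain_id", "T_K", "P_hPa", "ch4_ppbv", "r", "drG", "power_supply",
    "m_E", "net_gain", "doubling_time_yr", "threshold_ppbv",
]


@dataclass(frozen=True)
class RunConfig:
    """One orchestrated run: scenario grid, strain source, model parameters.

    Exactly one of ``strain_fixture``, ``strain_csv`` and ``strain_synth``
    must be set.
    """

    grid: EnvironmentGridSpec = field(default_factory=EnvironmentGridSpec)
    strain_fixture: bool = False
    strain_csv: str | None = None
    strain_synth: StrainEnsembleSpec | None = None
    maintenance: MaintenanceModel = field(default_factory=MaintenanceModel)
    biomass: BiomassEnergyParams = field(default_factory=BiomassEnergyParams)
    seed: int = 0
    outdir: str | None = None
    formats: tuple[str, ...] = ("csv",)

    def __post_init__(self) -> None:
        sources = sum(
            [bool(self.strain_fixture), self.strain_csv is not None,
             self.strain_synth is not None]
        )
        if sources != 1:
            raise ConfigurationError("exactly one strain source must be set")
        bad = set(self.formats) - {"csv", "json", "png"}
        if bad:
            raise ConfigurationError(f"unknown output formats: {sorted(bad)}")

    def strains(self) -> list[StrainKinetics]:
        if self.strain_fixture:
            return [lr1_fixture()]
        if self.strain_csv is not None:
            return read_strain_table(self.strain_csv)
        return sample_strain_ensemble(self.strain_synth)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        grid_kw = dict(raw.get("grid", {}))
        mix = _parse_mixing_ratios(raw.get("mixing_ratios"))
        if mix is not None:
            grid_kw["mix"] = mix
        for key in ("T_range", "P_range"):
            if key in grid_kw:
                grid_kw[key] = tuple(grid_kw[key])
        grid = EnvironmentGridSpec(**grid_kw)

        strains = dict(raw.get("strains", {"source": "lr1"}))
        source = strains.pop("source", "lr1")
        fixture, csv_path, synth = False, None, None
        if source == "lr1":
            fixture = True
        elif source == "csv":
            csv_path = strains.get("path")
            if not csv_path:
                raise ConfigurationError("strain source 'csv' requires a path")
        elif source == "synthetic":
            strains.setdefault("seed", raw.get("seed", 0))
            synth = StrainEnsembleSpec(**{
                k: tuple(v) if k in ("vmax_range", "kch4_range") else v
                for k, v in strains.items()
            })
        else:
            raise ConfigurationError(f"unknown strain source {source!r}")

        maint = MaintenanceModel(**raw.get("maintenance", {}))
        biomass = BiomassEnergyParams(**raw.get("biomass", {}))
        out = raw.get("output", {})
        return cls(
            grid=grid,
            strain_fixture=fixture,
            strain_csv=csv_path,
            strain_synth=synth,
            maintenance=maint,
            biomass=biomass,
            seed=int(raw.get("seed", 0)),
            outdir=out.get("dir"),
            formats=tuple(out.get("formats", ["csv"])),
        )


def _parse_mixing_ratios(raw: Mapping | None) -> dict[str, float] | None:
    """Scenario mixing-ratio dialect: v/v keys co2/o2/ch4, ppbv via ch4_ppbv."""
    if raw is None:
        return None
    mix = {}
    for key, val in raw.items():
        k = key.lower()
        if k == "ch4_ppbv":
            mix["CH4"] = float(val) * 1e-9
        elif k in ("co2", "o2", "ch4"):
            mix[k.upper()] = float(val)
        else:
            raise ConfigurationError(f"unknown mixing-ratio key {key!r}")
    return mix


def load_scenario_yaml(path: str | Path) -> AtmosphereState:
    """Read a single-scenario YAML (temperature_K, pressure_hPa, mixing_ratios)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    mix = _parse_mixing_ratios(raw.get("mixing_ratios"))
    if mix is None:
        raise ConfigurationError("scenario YAML requires mixing_ratios")
    return AtmosphereState.from_hpa(
        float(raw["temperature_K"]), float(raw["pressure_hPa"]), mix
    )


def _provenance(config: RunConfig, kind: str, extra: Mapping | None = None) -> str:
    payload = {
        "package": "methanomars",
        "version": __version__,
        "kind": kind,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
    }
    if extra:
        payload.update(extra)
    return "# provenance: " + json.dumps(payload, sort_keys=True, default=str)


def _write_outputs(
    df: pd.DataFrame, config: RunConfig, name: str, kind: str,
    extra: Mapping | None = None,
) -> None:
    if config.outdir is None:
        return
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = _provenance(config, kind, extra)
    if "csv" in config.formats:
        path = outdir / f"{name}.csv"
        with open(path, "w", newline="") as fh:
            fh.write(header + "\n")
            df.to_csv(fh, index=False, lineterminator="\n")
    if "json" in config.formats:
        payload = {
            "provenance": json.loads(header.removeprefix("# provenance: ")),
            "rows": json.loads(
                df.replace([math.inf, -math.inf], ["inf", "-inf"]).to_json(
                    orient="records"
                )
            ),
        }
        (outdir / f"{name}.json").write_text(json.dumps(payload, sort_keys=True))


def run_energy_map(config: RunConfig) -> pd.DataFrame:
    """Standard and in-situ Gibbs energies over the (T, P) grid.

    One row per node; nodes where the thermodynamic evaluation fails are
    reported with NaN values and the run continues.
    """
    species = default_species_table()
    if config.grid.T_range[0] < 273.15:
        logger.warning(
            "grid extends below 273.15 K: liquid-water heat capacity is the "
            "supercooled extrapolation of the fitted polynomial"
        )
    rows = []
    for atm in config.grid.atmospheres():
        try:
            rxn = delta_rG(species, atm)
            rows.append(
                {"T_K": atm.T, "P_hPa": atm.P_hPa,
                 "drG_standard": rxn.drG_standard, "drG": rxn.drG,
                 "Q_ln": rxn.Q_ln}
            )
        except MethanomarsError as exc:  # keep going, flag the node
            logger.warning("energy map node (%.2f K, %.2f hPa) failed: %s",
                           atm.T, atm.P_hPa, exc)
            rows.append(
                {"T_K": atm.T, "P_hPa": atm.P_hPa,
                 "drG_standard": math.nan, "drG": math.nan, "Q_ln": math.nan}
            )
    df = pd.DataFrame(rows)
    _write_outputs(df, config, "energy_map", "energy-map")
    if "png" in config.formats and config.outdir is not None:
        _plot_energy_map(df, Path(config.outdir) / "energy_map.png")
    return df


def run_viability(config: RunConfig) -> pd.DataFrame:
    """Net gain, threshold and doubling time per strain per grid node.

    Non-viable strains are kept in the table (infinite doubling time /
    threshold serialised as ``inf``); summary rows (mean/min/max across
    strains at each node) are appended with pseudo strain ids.
    """
    species = default_species_table()
    strains = config.strains()
    Y = biomass_synthesis_energy(config.biomass)
    rows = []
    for atm in config.grid.atmospheres():
        for strain in strains:
            budget = energy_budget(
                strain, atm, config.maintenance, Y=Y, species=species
            )
            threshold = minimum_ch4_threshold(
                strain, atm, config.maintenance, species=species
            )
            if budget.net_gain <= 0:
                logger.debug("%s not viable at (%.1f K, %.2f hPa)",
                             strain.strain_id, atm.T, atm.P_hPa)
            rows.append({
                "strain_id": strain.strain_id,
                "T_K": budget.T,
                "P_hPa": budget.P_hPa,
                "ch4_ppbv": budget.ch4_ppbv,
                "r": budget.rate_r,
                "drG": budget.drG,
                "power_supply": budget.power_supply,
                "m_E": budget.maintenance,
                "net_gain": budget.net_gain,
                "doubling_time_yr": budget.doubling_time_yr,
                "threshold_ppbv": threshold,
            })
    df = pd.DataFrame(rows, columns=VIABILITY_COLUMNS)
    numeric = [c for c in VIABILITY_COLUMNS if c not in ("strain_id",)]
    summaries = []
    for stat in ("mean", "min", "max"):
        agg = df.groupby(["T_K", "P_hPa"], as_index=False)[numeric].agg(stat)
        agg.insert(0, "strain_id", f"ensemble_{stat}")
        summaries.append(agg)
    out = pd.concat([df] + summaries, ignore_index=True)[VIABILITY_COLUMNS]
    _write_outputs(out, config, "viability", "viability")
    return out


def run_budget(
    config: RunConfig,
    production_flux: float,
    photochemical_loss: float,
    T: float = 230.0,
    P_hPa: float = 6.0,
) -> pd.DataFrame:
    """Areal CH4 sink budget: per-strain cell densities and biomass.

    The net microbial sink is production minus photochemical loss
    (molecules cm⁻² s⁻¹).  Densities are reported under both flux-to-rate
    conventions: ``density_per_hour`` converts the flux to mol cm⁻² h⁻¹
    before dividing by the per-hour cell rate (dimensionally consistent),
    ``density_published_convention`` divides the per-second molar flux by
    the per-hour rate, as the published ensemble figures imply.
    """
    sink = net_ch4_sink(production_flux, photochemical_loss)
    atm = AtmosphereState.from_hpa(T, P_hPa, config.grid.mix)
    cell_c = config.biomass.cell_carbon
    rows = []
    for strain in config.strains():
        dens_h = areal_cell_density(strain, atm, sink, per_hour=True)
        dens_s = areal_cell_density(strain, atm, sink, per_hour=False)
        rows.append({
            "strain_id": strain.strain_id,
            "T_K": T,
            "P_hPa": P_hPa,
            "sink_molecules_cm2_s": sink,
            "sink_mol_cm2_h": sink / AVOGADRO * SECONDS_PER_HOUR,
            "density_per_hour": dens_h,
            "density_published_convention": dens_s,
            "biomass_per_hour_gC_m2": areal_biomass(dens_h, cell_c),
            "biomass_published_convention_gC_m2": areal_biomass(dens_s, cell_c),
        })
    df = pd.DataFrame(rows)
    _write_outputs(
        df, config, "budget", "budget",
        extra={"production_flux": production_flux,
               "photochemical_loss": photochemical_loss},
    )
    return df


def _plot_energy_map(df: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), constrained_layout=True)
    for ax, col, title in zip(
        axes, ("drG_standard", "drG"),
        ("standard Gibbs energy", "in-situ Gibbs energy"),
    ):
        pivot = df.pivot_table(index="P_hPa", columns="T_K", values=col)
        im = ax.pcolormesh(pivot.columns, pivot.index, pivot.values, shading="auto")
        ax.set_xlabel("T (K)")
        ax.set_ylabel("P (hPa)")
        ax.set_title(f"{title} (kJ/mol CH4)")
        fig.colorbar(im, ax=ax)
    fig.savefig(path, dpi=120)
    plt.close(fig)
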