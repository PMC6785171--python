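# methanomars

Could aerobic methanotrophs — microbes that live by oxidising methane with
oxygen — survive in the upper regolith of present-day Mars? `methanomars`
answers this as a bioenergetic bookkeeping problem: it compares the rate at
which a cell can extract Gibbs energy from the reaction

```
CH4 + 2 O2  →  CO2 + 2 H2O(l)
```

under martian near-surface conditions (180–280 K, 6–11 hPa, 95% CO2,
0.145% O2, ppbv-level CH4) against the minimum power the cell needs just to
stay alive. It is written for geomicrobiologists and astrobiologists who
want a tested, scriptable version of this habitability calculation rather
than a spreadsheet.

## The model

Three ingredients are combined per cell, per environmental scenario:

1. **Thermodynamic driving force.** The in-situ Gibbs energy change
   ΔrG = ΔrG° + RT·ln[ f_CO2 / (f_O2² f_CH4) ], with ΔrG°(T, P) built from
   standard formation energies corrected via the Helgeson formulation
   (entropy term, closed-form heat-capacity integrals with
   Cp°/R = A + BT − CT², and an RT·ln(P/P\*) pressure term for gases).
   Fugacities follow the van der Waals correction; liquid water has unit
   activity.
2. **Kinetic rate.** Dual-substrate Michaelis–Menten kinetics
   r = v_max·[CH4]/(K_CH4+[CH4])·[O2]/(K_O2+[O2]) with gas concentrations
   [X] = γ_X·P/(RT). Strain parameters come from a CSV, the shipped
   *Methylocystis* sp. LR1 fixture, or a seeded log-uniform synthetic
   ensemble spanning the published 19-strain parameter ranges.
3. **Maintenance demand.** An Arrhenius law for the cell-specific
   maintenance energy rate, m_E = 10⁻¹⁵·exp(144.9 − 39 656/T) kJ cell⁻¹ h⁻¹,
   calibrated on sub-10 °C maintenance observations; the fitting machinery
   (`MaintenanceArrheniusModel(...).fit()`, statsmodels-style, with
   parameter CIs and a 95% confidence band) is part of the package.

From these follow the power supply −r·ΔrG, the net energy gain
−r·ΔrG − m_E, the minimum CH4 mixing ratio at which the gain is zero, the
cell doubling time Y·ln2/(−r·ΔrG − m_E) with Y the Heijnen biomass-synthesis
energy of one cell, and areal cell-density/biomass budgets from the net
planetary CH4 sink flux.

## Worked example

```python
import methanomars as mm

mars = mm.mars_default_atmosphere(T=230.0, P_hPa=6.0)   # 0.69 ppbv CH4
lr1 = mm.lr1_fixture()                                  # v_max 5e-17, K_CH4 2.5e-6

rxn = mm.delta_rG(mm.default_species_table(), mars)
budget = mm.energy_budget(lr1, mars)
threshold = mm.minimum_ch4_threshold(lr1, mars)

print(f"drG        = {rxn.drG:.1f} kJ/mol CH4")
print(f"power      = {budget.power_supply:.3e} kJ/cell/h")
print(f"m_E        = {budget.maintenance:.3e} kJ/cell/h")
print(f"doubling   = {budget.doubling_time_yr:.0f} Earth years")
print(f"threshold  = {threshold:.3e} ppbv CH4")
```

prints

```
drG        = -730.8 kJ/mol CH4
power      = 3.151e-21 kJ/cell/h
m_E        = 1.120e-27 kJ/cell/h
doubling   = 27281 Earth years
threshold  = 2.552e-07 ppbv CH4
```

Read: at 230 K the reaction is hugely exergonic, and although the CH4-starved
oxidation rate makes the power supply minuscule, the maintenance demand at
that temperature is six orders of magnitude smaller still — the strain can
survive on sub-ppbv methane (its threshold is ~10⁻⁷ ppbv), but doubling a
population would take tens of millennia.

The same surfaces are available from a shell:

```bash
methanomars energy-map --temp-K 298.15 --pressure-hPa 1013.25
methanomars viability --temp-K 230 --pressure-hPa 6 --out out/
methanomars budget --production-flux 8.8e5 --photochemical-loss 2.2e5
methanomars synth --seed 1 --out synth/        # strain CSV + scenario YAML
```

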