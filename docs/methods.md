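# Methods

## Model overview

The package treats microbial viability as a per-cell energy balance. A cell
is viable in a scenario when its catabolic power supply, −r·ΔrG, exceeds its
maintenance energy demand m_E(T); the surplus sets a minimum doubling time
via the energy cost Y of building one cell. Everything is steady-state and
zero-dimensional: no substrate drawdown, no population dynamics, no
transport. The soil-gas composition is assumed equal to the atmospheric one
(exposed as an override on the CH4 mixing ratio), which is reasonable while
outgassing fluxes are small enough to keep vertical gradients negligible
over the habitable depth.

## Thermodynamics

Formation energies are corrected from the 298.15 K / 1 bar reference state
with the Helgeson formulation

ΔfG°(T, P) = ΔfG°\* − S°\*(T − T\*) + ∫Cp° dT − T·∫Cp° dlnT + ∫V° dP.

A widely circulated variant of this expression omits the factor T on the
second integral; that form is dimensionally inconsistent and is not used
here. With Cp°/R = A + BT − CT² both temperature integrals have closed
forms; the test suite checks them against adaptive quadrature to below
10⁻⁶ kJ mol⁻¹ over 180–300 K. The pressure integral is RT·ln(P/P\*) for
gases (V° = RT/P) and V°·(P − P\*) for liquid water with constant
V° = 18×10⁻⁹ kJ Pa⁻¹ mol⁻¹.

The shipped species table carries CODATA/JANAF-grade constants:
ΔfG° = −394.36 (CO2 g), 0 (O2 g), −50.72 (CH4 g), −237.13 (H2O l) kJ mol⁻¹,
standard entropies, van der Waals a, b from standard tables, and A, B, C
coefficients obtained by least squares against reference heat-capacity
points over 180–320 K (H2O(l) over 273–320 K). These constants reproduce
ΔrG° = −817.90 kJ (mol CH4)⁻¹ at reference conditions. Liquid-water Cp
below 273.15 K is the extrapolation of the fitted polynomial — a
supercooled-liquid idealisation, flagged in debug logs and warned about
once per gridded run; its contribution to ΔrG° at 180 K is at the
few-kJ level, far below the ~−800 kJ signal.

Fugacities use the van der Waals correction
f_X = γ_X·P·exp{(γ_X·P/RT)(b − a/RT)}. At martian pressures (≤11 hPa) the
correction changes ΔrG by under 0.1 kJ mol⁻¹ (asserted as a test); it is
kept because the interfaces also evaluate Earth-pressure scenarios. Liquid
water enters the reaction quotient with activity 1.

Units: temperatures in K, internal pressures in atm with hPa accepted at
every interface (1 atm = 1013.25 hPa exactly); the reference pressure for
formation properties is 1 bar. Two gas constants are kept deliberately
(8.314×10⁻³ kJ K⁻¹ mol⁻¹ in energy contexts, 0.08206 L atm K⁻¹ mol⁻¹ in
volumetric ones). The reference temperature is 298.15 K throughout; source
material occasionally prints "298.13 K", which is treated as a typo — the
difference is far below every stated tolerance.

## Kinetics

r = v_max·g_CH4·g_O2 with g_X = [X]/(K_X + [X]) and [X] = γ_X·P/(RT).
Rates are per cell and per hour. K_O2 defaults to 1.9×10⁻⁹ mol L⁻¹ — the
only value reported for a methanotroph — for every strain. Laboratory
v_max and K values are extrapolated unchanged to low temperature; this is a
known, deliberate simplification (cold-adapted enzymes could be slower or,
after acclimation, comparable), and it biases energy gains optimistically.

## Maintenance energy

m_E(T) = p·exp(A − B/T) kJ cell⁻¹ h⁻¹ with defaults p = 10⁻¹⁵, A = 144.9,
B = 39 656 K. The prefactor is the mol-C content of one cell
(12 fg-C / 12.01 g mol⁻¹ ≈ 10⁻¹⁵ mol C), converting a per-mol-C law to per
cell. The defaults are the sub-10 °C calibration used for all headline
numbers; the calibration machinery itself is exposed:
`MaintenanceArrheniusModel` regresses ln m on 1/T by OLS (statsmodels),
excludes observations above T_max = 283.15 K, and reports parameter CIs and
the standard pointwise 95% confidence band of the regression line (the band
construction is a package choice; the source correlation does not specify
one). Carbon-turnover observations (gC gC⁻¹ h⁻¹) are converted to energy
units with the Gibbs cost of synthesising 1 gC of biomass — 291.4 kJ gC⁻¹
for autotrophic nitrifiers, the Heijnen value for heterotrophs' stated
carbon source — times 12.01 gC (mol C)⁻¹.

## Biomass energy and doubling time

Y = [200 + 18(6 − C)^1.8 + exp(|3.8 − γ|^0.32·(3.6 + 0.4C))]/12.01
kJ gC⁻¹, times the cellular carbon content (12 fg-C by default). For CH4
(C = 1, γ = 8) exact evaluation gives 1.0872×10⁻¹² kJ cell⁻¹. Doubling
time is Y·ln2 / (−r·ΔrG − m_E), converted with 8766 h per Earth year
(365.25 d, configurable); non-positive net gain maps to an explicit
infinity, never a negative time. No heat-dissipation efficiency factor is
applied by default (an optional multiplier defaults to 1), so doubling
times are minimum estimates.

## Minimum CH4 threshold

Setting the net gain to zero at fixed ΔrG gives the closed form
[CH4]\* = θ·K_CH4/(1 − θ) with θ = m_E/(v_max·g_O2·(−ΔrG)). Since ΔrG
depends only logarithmically on the CH4 mixing ratio (slope −RT per
e-fold), the closed form is iterated as a fixed point, recomputing ΔrG at
each candidate, to relative tolerance 10⁻⁸ (maximum 50 iterations —
convergence typically takes 3–4). Degenerate regimes are distinguished
explicitly: θ ≥ 1 at saturating CH4 means no CH4 level can cover
maintenance (infinite threshold); a root above the mixing-ratio headroom
left by CO2 + O2 is likewise reported infinite; and when maintenance is
negligible the kinetic root collapses onto the thermodynamic equilibrium
CH4 level (ΔrG = 0), which bounds the threshold from below and is returned
in that regime. Convergence failure raises instead of returning a sentinel,
so numeric trouble is never mistaken for non-viability. The fixed point is
cross-checked against a bisection root of the full net-gain equation on 20
random strains (10⁻⁶ relative agreement) in the test suite.

## Areal population budget

The net microbial CH4 sink is production minus photochemical loss
(molecules cm⁻² s⁻¹). Dividing the sink by the cell-specific rate gives a
sustaining cell density; done dimensionally consistently the flux is first
converted to mol cm⁻² h⁻¹ (Avogadro, 3600 s h⁻¹). Published ensemble
densities for this calculation are reproducible only if the per-second
molar flux is divided by the per-hour rate without the 3600 factor, so
`run_budget` reports both conventions side by side
(`density_per_hour` and `density_published_convention`) rather than
silently picking one. Biomass per area is density × cellular carbon with
fg→g and cm⁻²→m⁻² conversions.

## Synthetic data

The strain generator emulates a published 19-strain kinetic compilation
whose table is not redistributable: v_max and K_CH4 are drawn log-uniformly
within the printed ranges (5.6×10⁻¹⁸–5.7×10⁻¹⁶ mol cell⁻¹ h⁻¹ and
1.0×10⁻⁶–2.3×10⁻⁵ mol L⁻¹), independently by default. Log-uniform is the
neutral choice for scale parameters spanning two orders of magnitude; no
distributional information exists in the source. A correlation option
(Gaussian copula on the log scale, default 0) is exposed because the true
joint distribution is unknowable from the printed ranges. K_O2 is fixed at
1.9×10⁻⁹ mol L⁻¹. Synthetic maintenance datasets place multiplicative
lognormal noise on the Arrhenius mean — exactly the error structure the
log-linear OLS assumes — so fit-recovery tests validate the estimator, not
the realism of literature scatter (real observations mix organisms,
methods and digitisation error, and are unlikely to be homoscedastic in
the log). Passing tests therefore demonstrate correctness of the machinery
under the stated statistical assumptions, not that the maintenance law is
accurate for martian organisms.

All generators take integer seeds (numpy `default_rng`) and are
bit-reproducible on a platform. Ensemble-average quantities across the real
19 strains are *not* reproduced anywhere — they require the external table —
so ensemble-dependent published figures are used only as envelopes that the
fully-printed LR1 strain must respect.

## Orchestration and numerical hygiene

Gridded runs default to 51×51 over (180–280 K)×(6–11 hPa); tests and the
acceptance script use degenerate or coarse grids (single node to 5×5)
because every quantity is node-local and the fine grid adds only plotting
resolution. CSV outputs carry a single-line JSON provenance header (config
echo, seed, version; no timestamps) so identical configurations produce
byte-identical files. Infinities are serialised explicitly as `inf`.
Per-node thermodynamic failures in a gridded run are reported as NaN rows
and logged, not fatal. Plots (PNG) are conveniences; all results of record
are tabular.

## Known limitations

- Zero-dimensional, steady-state; no CH4 transport or drawdown, no
  localised high-concentration habitats.
- Kinetic and maintenance parameters are terrestrial lab values
  extrapolated to martian conditions without temperature correction.
- The maintenance calibration rests on very few sub-zero observations and
  one aerobic species on methanol; its confidence band is the OLS band,
  which understates structural uncertainty.
- Water activity is taken as 1; thin-film or brine activity corrections in
  regolith pores are out of scope.
- Radiation, desiccation, salinity and other stressors are not modelled;
  the analysis is an energy-balance necessary condition, not a sufficiency
  argument.
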