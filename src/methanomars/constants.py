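"""Physical constants and unit conversions used throughout the package.

Two values of the gas constant are deliberately kept side by side: the
energy-context value (kJ K⁻¹ mol⁻¹) enters Gibbs-energy expressions, while
the volumetric value (L atm K⁻¹ mol⁻¹) enters the van der Waals fugacity
correction and the ideal-gas concentration formula.  Keeping both as named
constants (rather than converting on the fly) prevents unit mix-ups.
"""

#: Gas constant in energy contexts, kJ K⁻¹ mol⁻¹.
R_KJ = 8.314e-3

#: Gas constant in volumetric contexts, L atm K⁻¹ mol⁻¹.
R_L_ATM = 0.08206

#: Reference temperature for standard-state properties, K.
T_REF = 298.15

#: hPa per atm (exact definition).
HPA_PER_ATM = 1013.25

#: Pa per atm (exact definition).
PA_PER_ATM = 101325.0

#: Reference pressure for formation properties: 1 bar, expressed in atm.
#: Scenario pressures are carried in atm; formation-property corrections are
#: taken relative to the 1 bar standard state.
P_REF_ATM = 1000.0 / HPA_PER_ATM

#: Avogadro constant, molecules mol⁻¹.
AVOGADRO = 6.02214076e23

SECONDS_PER_HOUR = 3600.0

#: Hours per Earth year (365.25 d); used for doubling-time conversion.
HOURS_PER_EARTH_YEAR = 8766.0

#: Stoichiometry of aerobic methane oxidation, CH4 + 2 O2 -> CO2 + 2 H2O,
#: normalised per mol CH4 (products positive, reactants negative).
STOICHIOMETRY = {"CO2": 1.0, "H2O": 2.0, "CH4": -1.0, "O2": -2.0}

#: Molar mass of carbon, g mol⁻¹.
CARBON_MOLAR_MASS = 12.01

#: Grams per femtogram.
G_PER_FG = 1e-15

#: cm² per m².
CM2_PER_M2 = 1e4


def hpa_to_atm(p_hpa: float) -> float:
    """Convert pressure from hPa to atm (exact constant)."""
    return p_hpa / HPA_PER_ATM


def atm_to_hpa(p_atm: float) -> float:
    """Convert pressure from atm to hPa (exact constant)."""
    return p_atm * HPA_PER_ATM
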