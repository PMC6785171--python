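"""Exception hierarchy.

``ThermodynamicDomainError`` marks physically invalid inputs (non-positive
temperature, liquid-phase fugacity requests, vanishing substrate in a
logarithm).  ``ConfigurationError`` marks structurally invalid inputs
(missing species, unknown phases or units).  ``FitError`` marks an
underdetermined or otherwise unusable regression problem.
"""


class MethanomarsError(Exception):
    """Base class for all package errors."""


class ThermodynamicDomainError(MethanomarsError, ValueError):
    """Physically invalid input to a thermodynamic or kinetic operation."""


class SubstrateAbsentError(ThermodynamicDomainError):
    """A reactant gas has zero mixing ratio where a logarithm is required."""


class ConfigurationError(MethanomarsError, ValueError):
    """Structurally invalid configuration (unknown species, phase, units...)."""


class FitError(MethanomarsError, ValueError):
    """Regression problem is underdetermined or has no usable data."""
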