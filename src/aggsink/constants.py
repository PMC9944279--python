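"""Physical constants and unit conversions.

The package works internally in cgs units (cm, g, s). Field-facing
quantities cross the boundary in the units practitioners use — aggregate
diameters in mm, settling velocities in m d⁻¹, excess densities in
mg cm⁻³ — and are converted explicitly at call sites.
"""

from __future__ import annotations

from dataclasses import dataclass

#: 1 cm s⁻¹ expressed in m d⁻¹ (0.01 m × 86400 s).
CM_S_TO_M_D = 864.0

#: 1 mm in cm.
MM_TO_CM = 0.1

#: Molar mass of carbon, g mol⁻¹ (µg → µmol conversion of POC).
CARBON_MOLAR_MASS = 12.011

#: Respiratory quotient: mol O₂ consumed per mol CO₂ produced.
RESPIRATORY_QUOTIENT = 1.2


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants entering Stokes' law, at the incubation temperature (17 °C).

    Attributes
    ----------
    kinematic_viscosity : float
        Kinematic viscosity of the ambient water, cm² s⁻¹.
    gravity : float
        Gravitational acceleration, cm s⁻².
    """

    kinematic_viscosity: float = 1.085e-2
    gravity: float = 981.0

    def __post_init__(self) -> None:
        if self.kinematic_viscosity <= 0 or self.gravity <= 0:
            raise ValueError("physical constants must be positive")


DEFAULT_CONSTANTS = PhysicalConstants()


def cylinder_volume_l(radius_cm: float, height_cm: float) -> float:
    """Volume of a rotating cylinder in litres (π r² h / 1000)."""
    import math

    if radius_cm <= 0 or height_cm <= 0:
        raise ValueError("cylinder dimensions must be positive")
    return math.pi * radius_cm**2 * height_cm / 1000.0
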