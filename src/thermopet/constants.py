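"""Physical constants and unit conversions used throughout the package.

All internal computation is in SI-adjacent units: Kelvin, J/mol, seconds.
Degrees Celsius, kJ/mol and K/min appear only at I/O boundaries and are
converted exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "PhysicalConstants",
    "CONSTANTS",
    "R",
    "CELSIUS_OFFSET",
    "celsius_to_kelvin",
    "kelvin_to_celsius",
]

#: Universal gas constant, J/(K mol), as used in every rate computation.
R = 8.314

#: Exact ITS-90 offset between degrees Celsius and Kelvin.
CELSIUS_OFFSET = 273.15


def _default_molar_masses() -> dict:
    # g/mol; standard chemistry values for the PET monomer products and the
    # repeat unit of the polymer (C10H8O4).
    return {
        "TPA": 166.13,
        "MHET": 210.18,
        "BHET": 254.24,
        "PET_repeat": 192.17,
    }


@dataclass(frozen=True)
class PhysicalConstants:
    """Immutable container of the constants the analyses share.

    Attributes
    ----------
    R : float
        Universal gas constant, J/(K mol). Fixed at 8.314.
    molar_mass : dict
        Molar masses in g/mol for TPA, MHET, BHET and the PET repeat unit.
    """

    R: float = R
    molar_mass: dict = field(default_factory=_default_molar_masses)

    def __post_init__(self) -> None:
        if self.R != 8.314:
            raise ValueError("gas constant is fixed at 8.314 J/(K mol)")


#: Shared default instance.
CONSTANTS = PhysicalConstants()


def celsius_to_kelvin(t_celsius):
    """Convert a temperature (scalar or array) from deg C to K."""
    return t_celsius + CELSIUS_OFFSET


def kelvin_to_celsius(t_kelvin):
    """Convert a temperature (scalar or array) from K to deg C."""
    return t_kelvin - CELSIUS_OFFSET
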