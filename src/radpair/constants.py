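"""Physical constants and unit conversions.

All magnetic flux densities in this package are stored in microtesla (μT)
and converted to angular frequency (rad s⁻¹) at a single point, via the
electron gyromagnetic ratio ``gamma_e = g_e * μB / ħ``.  The electron
g-value is fixed at the free-electron value 2.0023; μB, ħ, k_B and R are
CODATA 2018 values.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants used throughout the spin-dynamics model.

    Attributes
    ----------
    g_e : float
        Electron g-value (dimensionless). Both radicals are assigned the
        free-electron value; at geomagnetic field strengths the difference
        between the two radicals' g-values is negligible.
    bohr_magneton : float
        Bohr magneton μB, J T⁻¹.
    hbar : float
        Reduced Planck constant ħ, J s.
    k_B : float
        Boltzmann constant, J K⁻¹.
    R : float
        Molar gas constant, J mol⁻¹ K⁻¹.
    gamma_e : float
        Electron gyromagnetic ratio g_e·μB/ħ, rad s⁻¹ T⁻¹ (derived).
    """

    g_e: float = 2.0023
    bohr_magneton: float = 9.2740100783e-24
    hbar: float = 1.054571817e-34
    k_B: float = 1.380649e-23
    R: float = 8.31446261815324
    gamma_e: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "gamma_e", self.g_e * self.bohr_magneton / self.hbar
        )

    def omega_from_uT(self, b_uT: float) -> float:
        """Convert a magnetic flux density in μT to a Larmor angular
        frequency in rad s⁻¹ (ω = γe·B)."""
        return self.gamma_e * b_uT * 1e-6


#: Module-wide constant set; every conversion in the package goes through it.
CONSTANTS = PhysicalConstants()
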