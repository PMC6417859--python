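"""Order-of-magnitude context estimates.

Small closed-form calculations that place the simulated yield changes in
physical context: the electron Larmor precession that sets the timescale
for static-field sensitivity, the attenuation of an ELF field that is
randomly oriented rather than parallel to the static field, the
(negligible) thermodynamic alignment of a superparamagnetic nanoparticle
such as ferritin, and the distance along a north–south line over which
the geomagnetic field changes by a given amount.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from .constants import CONSTANTS

__all__ = [
    "OrientationConvention",
    "larmor",
    "randomly_oriented_effective_field_range",
    "superparamagnet_alignment_ratio",
    "geomagnetic_distance_equivalent",
]


@dataclass(frozen=True)
class OrientationConvention:
    """Angular-averaging convention for a randomly oriented ELF field.

    ``uniform_angle`` averages cos θ over θ uniform on (0, π/2), giving an
    effective amplitude factor 2/π ≈ 0.64; ``solid_angle`` weights by
    sin θ (uniform on the sphere), giving ⟨|cos θ|⟩ = 1/2.  The default
    elsewhere in the package is ``uniform_angle``.
    """

    mode: Literal["uniform_angle", "solid_angle"] = "uniform_angle"

    @property
    def amplitude_factor(self) -> float:
        if self.mode == "uniform_angle":
            return 2.0 / math.pi
        if self.mode == "solid_angle":
            return 0.5
        raise ValueError(f"unknown mode {self.mode!r}")


def larmor(B_uT: float) -> tuple[float, float]:
    """Electron Larmor frequency (Hz) and period (s) at field B (μT).

    At 50 μT the frequency is ≈1.4 MHz (period ≈700 ns): spin coherence
    must survive for a comparable time for a geomagnetic-strength field
    to affect the reaction yield.
    """
    if B_uT < 0:
        raise ValueError("B_uT must be non-negative")
    freq = CONSTANTS.omega_from_uT(B_uT) / (2.0 * math.pi)
    period = math.inf if freq == 0.0 else 1.0 / freq
    return freq, period


def randomly_oriented_effective_field_range(
    B0_uT: float,
    B1_uT: float,
    conv: OrientationConvention = OrientationConvention(),
) -> tuple[float, float, float]:
    """Total-field range for an ELF field randomly oriented w.r.t. B0.

    Returns ``(min_uT, max_uT, overestimate_factor)``: the field swings
    over B0 ∓ f·B1 with f the convention's amplitude factor, and since the
    ELF effect is quadratic in amplitude, assuming parallel alignment
    overestimates it by f⁻².
    """
    if B1_uT >= B0_uT:
        raise ValueError("requires B1 < B0")
    if B1_uT == 0.0:
        return B0_uT, B0_uT, 1.0
    f = conv.amplitude_factor
    return B0_uT - f * B1_uT, B0_uT + f * B1_uT, f**-2


def superparamagnet_alignment_ratio(
    moment_in_bohr_magnetons: float, B_uT: float, T: float
) -> float:
    """Magnetic-to-thermal energy ratio mB/kBT for a superparamagnetic
    moment (in units of μB) in a field B (μT) at temperature T (K).

    For ferritin (m ≈ 300 μB) in a 1 μT ELF field at body temperature
    this is ~1e-6: the nanoparticle cannot amplify the ELF field.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    return (
        moment_in_bohr_magnetons
        * CONSTANTS.bohr_magneton
        * B_uT
        * 1e-6
        / (CONSTANTS.k_B * T)
    )


def geomagnetic_distance_equivalent(
    delta_B_nT: float,
    B_pole_uT: float = 65.0,
    B_equator_uT: float = 25.0,
    circumference_km: float = 40000.0,
) -> tuple[float, float]:
    """Translate a field change (nT) into a north–south travel distance.

    The mean pole-to-equator gradient is (B_pole − B_equator) over a
    quarter circumference, ≈4 nT km⁻¹ for Earth; the distance is
    |ΔB|/gradient.
    Returns ``(gradient_nT_per_km, distance_km)``.
    """
    if circumference_km <= 0:
        raise ValueError("circumference must be positive")
    if B_pole_uT <= B_equator_uT:
        raise ValueError("requires B_pole > B_equator")
    gradient = (B_pole_uT - B_equator_uT) * 1e3 / (circumference_km / 4.0)
    return gradient, abs(delta_B_nT) / gradient
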