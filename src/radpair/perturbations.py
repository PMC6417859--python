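"""Temperature sensitivity of the triplet yield.

The two model parameters most plausibly temperature-dependent are the
reaction rate k and the spin-relaxation rate r.  The temperature effect is
defined as the fractional yield change under small rate increments,

    Te(Δk, Δr) = [ΦT(k+Δk, r+Δr) − ΦT(k, r)] / ΦT(k, r),

evaluated with no ELF field and no static offset.  A crude physiological
scale for Δk/k and Δr/r is 0.1% per °C; assuming Arrhenius kinetics,
rate ∝ exp(−Ea/RT), that fractional sensitivity corresponds to an
activation energy Ea = R·T²·(d ln rate/dT).
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import CONSTANTS
from .spin_core import (
    RadicalPairSystem,
    ReactionKinetics,
    SpectralCache,
    triplet_yield,
)

__all__ = ["RatePerturbation", "temperature_effect", "arrhenius_activation_energy"]


@dataclass(frozen=True)
class RatePerturbation:
    """Increments Δk, Δr (s⁻¹) applied to the reaction and relaxation
    rates."""

    dk: float = 0.0
    dr: float = 0.0

    def apply(self, kin: ReactionKinetics) -> ReactionKinetics:
        k = kin.k + self.dk
        r = kin.r + self.dr
        if k <= 0:
            raise ValueError(f"perturbed reaction rate k+dk = {k} must be positive")
        if r < 0:
            raise ValueError(f"perturbed relaxation rate r+dr = {r} must be non-negative")
        return ReactionKinetics(k=k, r=r)


def temperature_effect(
    system: RadicalPairSystem,
    kin: ReactionKinetics,
    pert: RatePerturbation,
    B0_uT: float = 50.0,
    *,
    cache: SpectralCache | None = None,
) -> float:
    """Fractional yield change Te under rate increments, at static field
    B0 and no ELF field.  The Δk-only and Δr-only effects are additive to
    first order."""
    if cache is None:
        cache = SpectralCache()
    spec = cache.get(system, B0_uT)
    phi0 = triplet_yield(spec, kin)
    phi1 = triplet_yield(spec, pert.apply(kin))
    return (phi1 - phi0) / phi0


def arrhenius_activation_energy(
    fractional_change_per_K: float, T: float
) -> tuple[float, float]:
    """Activation energy implied by a fractional rate sensitivity.

    Parameters
    ----------
    fractional_change_per_K : float
        d ln(rate)/dT in K⁻¹ (e.g. 0.001 for 0.1% per °C).
    T : float
        Absolute temperature, K.

    Returns
    -------
    (Ea, Ea_over_RT)
        Activation energy in J mol⁻¹ and the dimensionless ratio Ea/RT.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    Ea = CONSTANTS.R * T * T * fractional_change_per_K
    return Ea, Ea / (CONSTANTS.R * T)
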