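"""Brute-force cross-checks for the spectral yield formulas (test-only).

Two independent routes to the same quantities:

* :func:`propagate_triplet_probability` evolves the singlet-born density
  operator ρ(0) = P̂S/M by explicit matrix exponentials and measures
  1 − Tr[P̂S ρ(t)] — no eigenbasis cosine sum.
* :func:`yield_numeric` integrates k·pT(t)·e^(−kt) over time by composite
  Gauss–Legendre quadrature with panel-doubling, instead of using the
  closed-form Lorentzian sum.

These are deliberately slow; they exist so the production code can be
checked against arithmetic that shares none of its shortcuts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .errors import NumericalAccuracyError
from .spin_core import (
    RadicalPairSystem,
    ReactionKinetics,
    build_hamiltonian,
    singlet_projector,
    spectral_decomposition,
    triplet_probability,
)

__all__ = ["PropagationResult", "propagate_triplet_probability", "yield_numeric"]


@dataclass(frozen=True)
class PropagationResult:
    """Triplet probabilities from direct unitary propagation."""

    times: np.ndarray
    pT_values: np.ndarray


def propagate_triplet_probability(
    system: RadicalPairSystem,
    B_uT: float,
    times: np.ndarray,
) -> PropagationResult:
    """Coherent triplet probability pT′(t) by matrix exponentials.

    The initial ensemble is the maximally mixed nuclear state within the
    electron-singlet subspace, ρ(0) = P̂S/M; each requested time gets its
    own U = exp(−iHt).
    """
    t_arr = np.asarray(times, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("times must be non-negative")
    H = build_hamiltonian(system, B_uT)
    P = singlet_projector(system)
    rho0 = P / np.trace(P).real
    vals = np.empty(t_arr.size)
    for i, t in enumerate(t_arr.ravel()):
        U = expm(-1j * H * t)
        rho_t = U @ rho0 @ U.conj().T
        vals[i] = 1.0 - np.real(np.trace(P @ rho_t))
    return PropagationResult(times=t_arr, pT_values=vals.reshape(t_arr.shape))


def yield_numeric(
    system: RadicalPairSystem,
    B_uT: float,
    kin: ReactionKinetics,
    *,
    rtol: float = 1e-8,
    nodes_per_panel: int = 16,
    max_refinements: int = 6,
) -> float:
    """Triplet yield by time-domain quadrature of k·pT(t)·e^(−kt).

    The integral is truncated at T_max = 40/k (neglected tail below
    e⁻⁴⁰) and evaluated by composite Gauss–Legendre quadrature.  The
    initial panel count resolves the fastest coherence oscillation; the
    count is doubled until two successive estimates agree to ``rtol``.
    """
    spec = spectral_decomposition(system, B_uT)
    k, r = kin.k, kin.r
    t_max = 40.0 / k

    omega_span = float(spec.omegas[-1] - spec.omegas[0])
    n_osc = omega_span * t_max / (2.0 * np.pi)
    panels = max(32, int(np.ceil(2.0 * n_osc)))

    x, w = np.polynomial.legendre.leggauss(nodes_per_panel)

    def integrate(n_panels: int) -> float:
        edges = np.linspace(0.0, t_max, n_panels + 1)
        total = 0.0
        for a, b in zip(edges[:-1], edges[1:]):
            t = 0.5 * (b - a) * x + 0.5 * (a + b)
            pt = triplet_probability(spec, t, r)
            total += 0.5 * (b - a) * np.sum(w * k * pt * np.exp(-k * t))
        return total

    prev = integrate(panels)
    for _ in range(max_refinements):
        panels *= 2
        cur = integrate(panels)
        if abs(cur - prev) <= rtol * max(abs(cur), 1e-300):
            return cur
        prev = cur
    raise NumericalAccuracyError(
        "time-domain quadrature for the triplet yield did not converge",
        estimates=(prev, cur),
    )
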