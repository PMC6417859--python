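"""Magnetic-field effects on the triplet yield.

Two fractional yield changes are computed for a radical pair sitting in a
static (geomagnetic) field B0:

* ``mfeELF`` — the effect of a weak 50/60 Hz field of peak amplitude B1
  superimposed parallel to B0.  Because magnetically sensitive radical
  pairs live microseconds while the ELF period is 20 ms, each pair sees an
  effectively static field B = B0 + B1·cos α with random phase α, and the
  ensemble yield is the phase average Φ̄T = (1/π)∫₀^π ΦT(B0+B1 cos α) dα.
  For B1 ≪ B0 a second-order Taylor expansion gives
  mfeELF ≈ ¼ B1² ΦT″(B0)/ΦT(B0): the ELF effect probes the *curvature* of
  the yield curve and scales quadratically in B1.

* ``mfeGMF`` — the effect of a small static offset ΔB0, either as the
  exact yield difference or linearised as ΔB0·ΦT′(B0)/ΦT(B0): it probes
  the *gradient* and is linear in ΔB0.

Yield derivatives are obtained by Richardson-extrapolated central finite
differences with a convergence guard; the eigendecompositions at the
stencil fields are cached and shared across lifetime sweeps, since the
kinetic constants enter the yield formula only after diagonalisation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np

from .errors import DegenerateExtremumError, NumericalAccuracyError
from .spin_core import (
    RadicalPairSystem,
    ReactionKinetics,
    SpectralCache,
    spectral_decomposition,
    triplet_yield,
)

__all__ = [
    "FieldProtocol",
    "MfeResult",
    "SweepResult",
    "phi_vs_field",
    "phi_derivative",
    "mfe_elf_taylor",
    "mfe_elf_quadrature",
    "mfe_gmf",
    "lifetime_extremum",
    "omega_ratio",
    "equivalent_static_change",
]

#: Taylor expansions around B0 are only trusted for perturbations below
#: this fraction of the static field.
TAYLOR_BOUND = 0.2


@dataclass(frozen=True)
class FieldProtocol:
    """Field conditions: static field B0, ELF peak amplitude B1 and static
    offset ΔB0, all in μT.

    Defaults are the reference conditions of the model: a 50 μT
    geomagnetic field, a 1 μT peak ELF amplitude (the epidemiological
    exposure threshold of ~0.7 μT rms), and a −1 μT static offset chosen
    so the two effects usually share a sign.
    """

    B0_uT: float = 50.0
    B1_uT: float = 1.0
    dB0_uT: float = -1.0

    def __post_init__(self) -> None:
        if self.B0_uT <= 0:
            raise ValueError(f"B0_uT must be positive, got {self.B0_uT}")
        if self.B1_uT < 0:
            raise ValueError(f"B1_uT must be non-negative, got {self.B1_uT}")

    def require_taylor_valid(self, need_b1: bool = False, need_db0: bool = False) -> None:
        if need_b1 and self.B1_uT > TAYLOR_BOUND * self.B0_uT:
            raise ValueError(
                f"B1 = {self.B1_uT} μT exceeds the Taylor validity bound "
                f"{TAYLOR_BOUND}·B0 = {TAYLOR_BOUND * self.B0_uT} μT; "
                "use the quadrature route instead"
            )
        if need_db0 and abs(self.dB0_uT) > TAYLOR_BOUND * self.B0_uT:
            raise ValueError(
                f"|ΔB0| = {abs(self.dB0_uT)} μT exceeds the Taylor validity "
                f"bound {TAYLOR_BOUND}·B0 = {TAYLOR_BOUND * self.B0_uT} μT"
            )


@dataclass(frozen=True)
class MfeResult:
    """A fractional triplet-yield change.

    ``value`` is dimensionless; ``ppm`` is the same number ×10⁶.
    ``phi_ref`` is the reference yield ΦT(B0) the change is relative to.
    """

    value: float
    method: Literal["taylor", "quadrature", "exact_difference", "linear"]
    tau_s: float
    phi_ref: float

    @property
    def ppm(self) -> float:
        return self.value * 1e6


@dataclass(frozen=True)
class SweepResult:
    """A 1-D parameter sweep of a yield or yield-change quantity."""

    axis_name: str
    axis_values: np.ndarray
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ax = np.asarray(self.axis_values, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if ax.size != vals.size:
            raise ValueError("axis_values and values must have equal length")
        if ax.size == 0:
            raise ValueError("sweep must contain at least one point")
        d = np.diff(ax)
        if ax.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("axis_values must be strictly monotone")
        object.__setattr__(self, "axis_values", ax)
        object.__setattr__(self, "values", vals)

    def to_csv(self, path: str | Path) -> None:
        """Write the sweep as CSV with '#'-prefixed metadata header lines.

        Floats use a round-trip format, so re-parsing reproduces the
        numeric columns exactly.
        """
        path = Path(path)
        lines = [f"# {k} = {v}" for k, v in sorted(self.metadata.items())]
        lines.append(f"{self.axis_name},value")
        for x, y in zip(self.axis_values, self.values):
            lines.append(f"{float(x)!r},{float(y)!r}")
        path.write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SweepResult":
        meta: dict = {}
        rows: list[tuple[float, float]] = []
        axis_name = "axis"
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = val.strip()
            elif "," in line and not line[0].isdigit() and not line[0] in "+-.":
                axis_name = line.split(",")[0]
            else:
                a, b = line.split(",")
                rows.append((float(a), float(b)))
        ax, vals = zip(*rows)
        return cls(axis_name=axis_name, axis_values=np.array(ax),
                   values=np.array(vals), metadata=meta)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "axis_name": self.axis_name,
            "axis_values": self.axis_values.tolist(),
            "values": self.values.tolist(),
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _phi_at(
    system: RadicalPairSystem,
    kin: ReactionKinetics,
    B_uT: float,
    cache: SpectralCache | None,
) -> float:
    if cache is not None:
        return triplet_yield(cache.get(system, B_uT), kin)
    return triplet_yield(spectral_decomposition(system, B_uT), kin)


def phi_vs_field(
    system: RadicalPairSystem,
    kin: ReactionKinetics,
    B_grid_uT: Sequence[float],
) -> SweepResult:
    """Triplet yield ΦT on a grid of static field strengths (μT).

    At intermediate lifetimes (τ ≈ 1 μs) the curve is bi-phasic: the
    low-field effect raises ΦT below ~1 mT before the high-field
    Zeeman-isolation regime lowers it.
    """
    grid = np.asarray(B_grid_uT, dtype=float)
    if grid.size == 0:
        raise ValueError("B_grid_uT must not be empty")
    if np.any(grid < 0):
        raise ValueError("field grid values must be non-negative")
    vals = np.array(
        [triplet_yield(spectral_decomposition(system, b), kin) for b in grid]
    )
    return SweepResult(
        axis_name="B0_uT",
        axis_values=grid,
        values=vals,
        metadata={
            "system": system.name,
            "k_per_s": kin.k,
            "r_per_s": kin.r,
            "quantity": "Phi_T",
        },
    )


def phi_derivative(
    system: RadicalPairSystem,
    kin: ReactionKinetics,
    B0_uT: float,
    order: int = 1,
    *,
    h_uT: float = 0.05,
    rtol: float = 1e-3,
    atol: float = 1e-9,
    max_halvings: int = 4,
    cache: SpectralCache | None = None,
) -> float:
    """n-th derivative of ΦT with respect to B at B0, per μT^order.

    Central differences at steps h, h/2, …; the two finest raw estimates
    must agree to ``rtol`` relative (or ``atol`` absolute, for flat
    responses), and the returned value is their Richardson extrapolation.

    Raises
    ------
    NumericalAccuracyError
        If the stencil does not converge within ``max_halvings``.
    """
    if B0_uT <= 0:
        raise ValueError("B0_uT must be positive")
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if cache is None:
        cache = SpectralCache()

    def estimate(h: float) -> float:
        up = _phi_at(system, kin, B0_uT + h, cache)
        dn = _phi_at(system, kin, B0_uT - h, cache)
        if order == 1:
            return (up - dn) / (2 * h)
        mid = _phi_at(system, kin, B0_uT, cache)
        return (up - 2 * mid + dn) / (h * h)

    prev = estimate(h_uT)
    h = h_uT
    for _ in range(max_halvings):
        h /= 2
        cur = estimate(h)
        if abs(cur - prev) <= max(rtol * abs(cur), atol):
            # both stencils are O(h²); one Richardson step cancels that term
            return (4 * cur - prev) / 3
        prev = cur
    raise NumericalAccuracyError(
        f"finite-difference stencil for ΦT derivative (order {order}) did "
        f"not converge at B0 = {B0_uT} μT",
        estimates=(prev, cur),
    )


def mfe_elf_taylor(
    system: RadicalPairSystem,
    kin: ReactionKinetics,
    proto: FieldProtocol,
    *,
    cache: SpectralCache | None = None,
) -> MfeResult:
    """ELF yield change from the curvature: mfeELF ≈ ¼B1²·ΦT″(B0)/ΦT(B0)."""
    proto.require_taylor_valid(need_b1=True)
    if cache is None:
        cache = SpectralCache()
    phi0 = _phi_at(system, kin, proto.B0_uT, cache)
    if proto.B1_uT == 0.0:
        return MfeResult(0.0, "taylor", kin.tau, phi0)
    d2 = phi_derivative(system, kin, proto.B0_uT, order=2, cache=cache)
    value = 0.25 * proto.B1_uT**2 * d2 / phi0
    return MfeResult(value, "taylor", kin.tau, phi0)


def mfe_elf_quadrature(
    system: RadicalPairSystem,
    kin: ReactionKinetics,
    proto: FieldProtocol,
    *,
    n_nodes: int = 20,
    rtol: float = 1e-4,
    max_doublings: int = 4,
    cache: SpectralCache | None = None,
) -> MfeResult:
    """ELF yield change by explicit phase averaging over α ∈ (0, π).

    Gauss–Legendre quadrature of (1/π)∫ΦT(B0 + B1 cos α)dα; node count is
    doubled until the mfe estimate changes by less than ``rtol`` relative.
    Valid for any B1 < B0 (no Taylor assumption).
    """
    if proto.B1_uT >= proto.B0_uT:
        raise ValueError("quadrature route requires B1 < B0")
    if cache is None:
        cache = SpectralCache()
    phi0 = _phi_at(system, kin, proto.B0_uT, cache)
    if proto.B1_uT == 0.0:
        return MfeResult(0.0, "quadrature", kin.tau, phi0)

    def average(n: int) -> float:
        x, w = np.polynomial.legendre.leggauss(n)
        alpha = 0.5 * math.pi * (x + 1.0)
        weights = 0.5 * w  # ∫₀^π f dα / π  with α = π(x+1)/2
        fields = proto.B0_uT + proto.B1_uT * np.cos(alpha)
        phis = np.array([_phi_at(system, kin, b, cache) for b in fields])
        return float(np.sum(weights * phis))

    n = n_nodes
    prev = average(n)
    for _ in range(max_doublings):
        n *= 2
        cur = average(n)
        mfe_prev = (prev - phi0) / phi0
        mfe_cur = (cur - phi0) / phi0
        if abs(mfe_cur - mfe_prev) <= max(rtol * abs(mfe_cur), 1e-15):
            return MfeResult(mfe_cur, "quadrature", kin.tau, phi0)
        prev = cur
    raise NumericalAccuracyError(
        "phase-average quadrature for mfeELF did not converge",
        estimates=(mfe_prev, mfe_cur),
    )


def mfe_gmf(
    system: RadicalPairSystem,
    kin: ReactionKinetics,
    proto: FieldProtocol,
    method: Literal["exact_difference", "linear"] = "linear",
    *,
    cache: SpectralCache | None = None,
) -> MfeResult:
    """Yield change for a static offset ΔB0 of the geomagnetic field.

    ``exact_difference`` evaluates (ΦT(B0+ΔB0) − ΦT(B0))/ΦT(B0);
    ``linear`` uses the gradient, ΔB0·ΦT′(B0)/ΦT(B0).
    """
    if abs(proto.dB0_uT) >= proto.B0_uT:
        raise ValueError("|ΔB0| must be smaller than B0")
    if cache is None:
        cache = SpectralCache()
    phi0 = _phi_at(system, kin, proto.B0_uT, cache)
    if proto.dB0_uT == 0.0:
        return MfeResult(0.0, method, kin.tau, phi0)
    if method == "exact_difference":
        phi1 = _phi_at(system, kin, proto.B0_uT + proto.dB0_uT, cache)
        value = (phi1 - phi0) / phi0
    elif method == "linear":
        proto.require_taylor_valid(need_db0=True)
        d1 = phi_derivative(system, kin, proto.B0_uT, order=1, cache=cache)
        value = proto.dB0_uT * d1 / phi0
    else:
        raise ValueError(f"unknown method {method!r}")
    return MfeResult(value, method, kin.tau, phi0)


def _mfe_of_tau(
    system: RadicalPairSystem,
    r: float,
    proto: FieldProtocol,
    mode: Literal["elf", "gmf"],
    cache: SpectralCache,
) -> Callable[[float], MfeResult]:
    def f(tau: float) -> MfeResult:
        kin = ReactionKinetics.from_lifetime(tau, r)
        if mode == "elf":
            return mfe_elf_taylor(system, kin, proto, cache=cache)
        return mfe_gmf(system, kin, proto, method="linear", cache=cache)

    return f


def lifetime_extremum(
    system: RadicalPairSystem,
    r: float,
    proto: FieldProtocol,
    mode: Literal["elf", "gmf"],
    tau_range: tuple[float, float] = (1e-9, 1e-3),
    *,
    points_per_decade: int = 25,
    tau_rtol: float = 1e-3,
    cache: SpectralCache | None = None,
) -> tuple[float, MfeResult]:
    """Signed mfe of largest magnitude over a range of lifetimes.

    A log-spaced τ grid locates the global |mfe| maximum, then a
    golden-section refinement in log τ narrows the bracket to a relative
    width of ``tau_rtol``.  All τ evaluations share one spectral cache:
    the rate constant only enters the Lorentzian sum, not the
    eigendecomposition.

    Raises
    ------
    DegenerateExtremumError
        If the response is flat (|mfe| < 1e-12 everywhere), as for a
        system with no hyperfine couplings.
    """
    t_lo, t_hi = tau_range
    if not (0 < t_lo < t_hi):
        raise ValueError("tau_range must be positive with min < max")
    if mode not in ("elf", "gmf"):
        raise ValueError(f"unknown mode {mode!r}")
    if cache is None:
        cache = SpectralCache()
    f = _mfe_of_tau(system, r, proto, mode, cache)

    decades = math.log10(t_hi / t_lo)
    n = max(2, int(math.ceil(points_per_decade * decades)) + 1)
    taus = np.logspace(math.log10(t_lo), math.log10(t_hi), n)
    mags = np.array([abs(f(t).value) for t in taus])
    if np.max(mags) < 1e-12:
        raise DegenerateExtremumError(
            f"no magnetic field response above 1e-12 for {system.name} "
            f"({mode} mode); the yield is field-independent"
        )
    i = int(np.argmax(mags))
    lo = math.log(taus[max(i - 1, 0)])
    hi = math.log(taus[min(i + 1, n - 1)])

    # golden-section maximisation of |mfe| on log-lifetime
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = abs(f(math.exp(c)).value)
    fd = abs(f(math.exp(d)).value)
    while (b - a) > tau_rtol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = abs(f(math.exp(c)).value)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = abs(f(math.exp(d)).value)
    tau_star = math.exp(0.5 * (a + b))
    return tau_star, f(tau_star)


def omega_ratio(
    system: RadicalPairSystem,
    r: float,
    B0_uT: float = 50.0,
    B1_uT: float = 1.0,
    dB0_uT: float = -1.0,
    tau_range: tuple[float, float] = (1e-9, 1e-3),
    *,
    cache: SpectralCache | None = None,
) -> float:
    """Ω = mfeGMFmax / mfeELFmax, each extremised over τ independently."""
    if cache is None:
        cache = SpectralCache()
    proto = FieldProtocol(B0_uT=B0_uT, B1_uT=B1_uT, dB0_uT=dB0_uT)
    _, elf = lifetime_extremum(system, r, proto, "elf", tau_range, cache=cache)
    _, gmf = lifetime_extremum(system, r, proto, "gmf", tau_range, cache=cache)
    if elf.value == 0.0:
        raise ZeroDivisionError("mfeELFmax is zero; Ω undefined")
    return gmf.value / elf.value


def equivalent_static_change(omega: float, B1_uT: float) -> float:
    """Static geomagnetic offset (nT) with the same fractional yield
    change as an ELF field of peak amplitude B1, given Ω.

    The sign matches mfeELF: a positive Ω (effects of like sign) maps the
    ELF field onto a *decrease* of the static field when ΔB0 < 0 was used
    to define Ω.
    """
    if omega == 0.0:
        raise ZeroDivisionError("Ω must be nonzero")
    return -B1_uT * 1e3 / omega
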