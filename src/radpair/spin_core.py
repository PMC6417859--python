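"""Spin operators, the radical-pair Hamiltonian, and triplet yields.

The model is a pair of unpaired electron spins (one per radical) coupled
isotropically to a small set of nuclear spins.  In an external static field
B the spin Hamiltonian (angular-frequency units, rad s⁻¹) is

    H = ω (S_Az + S_Bz) + Σₙ aₙ Ŝ·Îₙ ,        ω = γe·B,

with isotropic hyperfine couplings aₙ given in field units (μT) and
converted through the same gyromagnetic ratio.  Anisotropic hyperfine
components, electron–electron exchange/dipolar couplings and nuclear
Zeeman terms are all omitted: they are either irrelevant for freely
tumbling or immobilised-but-unaligned radicals at geomagnetic field
strengths, or act to suppress the magnetic field effects this model is
used to bound.

For a pair born in the electron singlet state, the probability of finding
it in a triplet state after a coherent evolution time t is obtained from
the eigensystem {|m⟩, ω_m} of H:

    pT′(t) = 1 − (1/M) Σ_mn |⟨m|P̂S|n⟩|² cos[(ω_m − ω_n) t],

where P̂S = ¼𝟙 − Ŝ_A·Ŝ_B projects onto the electron-singlet subspace and
M is the number of nuclear spin configurations.  Spin relaxation is
phenomenological — exponential decay toward the 1:3 singlet:triplet
equilibrium with rate r — and both reaction channels share one first-order
rate constant k (the exponential model), giving the closed-form triplet
yield

    ΦT = ¾ + k/[4(k+r)] − (1/M) Σ_mn w_mn · k(k+r)/[(k+r)² + (ω_m−ω_n)²].
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce
from typing import Sequence

import numpy as np

from .constants import CONSTANTS

__all__ = [
    "Nucleus",
    "RadicalPairSystem",
    "ReactionKinetics",
    "SpectralDecomposition",
    "SpectralCache",
    "angular_momentum_operators",
    "build_hamiltonian",
    "singlet_projector",
    "spectral_decomposition",
    "triplet_probability",
    "triplet_yield",
]


def angular_momentum_operators(
    multiplicity: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spin angular-momentum matrices (Jx, Jy, Jz) for a spin of the given
    multiplicity 2I+1, in the |I, m⟩ basis ordered m = I … −I.

    Raises
    ------
    ValueError
        If ``multiplicity`` is less than 2.
    """
    if multiplicity < 2:
        raise ValueError(f"multiplicity must be >= 2, got {multiplicity}")
    I = (multiplicity - 1) / 2.0
    m = I - np.arange(multiplicity)
    jz = np.diag(m).astype(complex)
    # ladder operator J+ connects m to m+1: <m+1|J+|m> = sqrt(I(I+1) - m(m+1))
    off = np.sqrt(I * (I + 1) - m[1:] * (m[1:] + 1))
    jplus = np.zeros((multiplicity, multiplicity), dtype=complex)
    jplus[np.arange(multiplicity - 1), np.arange(1, multiplicity)] = off
    jx = (jplus + jplus.conj().T) / 2
    jy = (jplus - jplus.conj().T) / (2j)
    return jx, jy, jz


@dataclass(frozen=True)
class Nucleus:
    """A nuclear spin coupled isotropically to one of the two electrons.

    Parameters
    ----------
    label : str
        Name of the nucleus (e.g. ``"N5"``).
    spin : float
        Nuclear spin quantum number I; a non-negative half-integer.
    coupling_uT : float
        Isotropic hyperfine coupling constant a, in μT.
    electron : str
        ``"A"`` or ``"B"``, the electron this nucleus couples to.
    """

    label: str
    spin: float
    coupling_uT: float
    electron: str

    def __post_init__(self) -> None:
        mult = 2 * self.spin + 1
        if self.spin < 0 or abs(mult - round(mult)) > 1e-12:
            raise ValueError(f"spin must be a non-negative half-integer, got {self.spin}")
        if self.electron not in ("A", "B"):
            raise ValueError(f"electron must be 'A' or 'B', got {self.electron!r}")
        if not np.isfinite(self.coupling_uT):
            raise ValueError("coupling_uT must be finite")

    @property
    def multiplicity(self) -> int:
        return int(round(2 * self.spin + 1))


@dataclass(frozen=True)
class RadicalPairSystem:
    """A two-electron, N-nucleus radical pair born in the electron singlet.

    Operators live on the tensor-product space ordered
    electron A ⊗ electron B ⊗ nuclei (declaration order), with magnetic
    quantum numbers descending within each factor.
    """

    name: str
    nuclei: tuple[Nucleus, ...]

    def __init__(self, name: str, nuclei: Sequence[Nucleus] = ()) -> None:
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "nuclei", tuple(nuclei))

    @property
    def nuclear_multiplicities(self) -> tuple[int, ...]:
        return tuple(n.multiplicity for n in self.nuclei)

    @property
    def n_configurations(self) -> int:
        """M, the number of nuclear spin configurations Π(2Iᵢ+1)."""
        return int(np.prod(self.nuclear_multiplicities, dtype=np.int64)) if self.nuclei else 1

    @property
    def dimension(self) -> int:
        """Hilbert-space dimension 4·M."""
        return 4 * self.n_configurations

    def fingerprint(self) -> tuple:
        """Hashable identity used as a cache key."""
        return (self.name,) + tuple(
            (n.label, n.spin, n.coupling_uT, n.electron) for n in self.nuclei
        )


@dataclass(frozen=True)
class ReactionKinetics:
    """First-order reaction rate k and phenomenological spin-relaxation
    rate r, both in s⁻¹.  The radical-pair lifetime is τ = 1/k."""

    k: float
    r: float = 0.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"reaction rate k must be positive, got {self.k}")
        if self.r < 0:
            raise ValueError(f"relaxation rate r must be non-negative, got {self.r}")

    @property
    def tau(self) -> float:
        return 1.0 / self.k

    @classmethod
    def from_lifetime(cls, tau: float, r: float = 0.0) -> "ReactionKinetics":
        return cls(k=1.0 / tau, r=r)


def _embed(ops: Sequence[np.ndarray | None], dims: Sequence[int]) -> np.ndarray:
    """Kronecker-embed single-site operators into the full product space.

    ``ops[i]`` is the operator on site i or None for identity; ``dims`` are
    the site dimensions in tensor order.
    """
    mats = [
        op if op is not None else np.eye(d, dtype=complex)
        for op, d in zip(ops, dims)
    ]
    return reduce(np.kron, mats)


def _site_dims(system: RadicalPairSystem) -> list[int]:
    return [2, 2] + list(system.nuclear_multiplicities)


def _electron_vector_ops(system: RadicalPairSystem, which: str) -> list[np.ndarray]:
    """(Sx, Sy, Sz) of electron A or B embedded in the full space."""
    dims = _site_dims(system)
    idx = 0 if which == "A" else 1
    out = []
    for comp in angular_momentum_operators(2):
        ops: list[np.ndarray | None] = [None] * len(dims)
        ops[idx] = comp
        out.append(_embed(ops, dims))
    return out


def build_hamiltonian(system: RadicalPairSystem, B_uT: float) -> np.ndarray:
    """Spin Hamiltonian in rad s⁻¹ at static field ``B_uT`` (μT).

    Zeeman term ω(S_Az + S_Bz) plus isotropic hyperfine terms aₙ Ŝ·Îₙ;
    couplings are converted from μT with the same γe as the field.
    """
    if B_uT < 0:
        raise ValueError(f"B_uT must be non-negative, got {B_uT}")
    dims = _site_dims(system)
    dim = int(np.prod(dims))
    H = np.zeros((dim, dim), dtype=complex)

    omega = CONSTANTS.omega_from_uT(B_uT)
    sz = angular_momentum_operators(2)[2]
    for e_idx in (0, 1):
        ops: list[np.ndarray | None] = [None] * len(dims)
        ops[e_idx] = sz
        H += omega * _embed(ops, dims)

    e_components = {"A": angular_momentum_operators(2), "B": angular_momentum_operators(2)}
    for n_idx, nuc in enumerate(system.nuclei):
        a = CONSTANTS.omega_from_uT(nuc.coupling_uT)
        e_idx = 0 if nuc.electron == "A" else 1
        i_ops = angular_momentum_operators(nuc.multiplicity)
        for s_comp, i_comp in zip(e_components[nuc.electron], i_ops):
            ops = [None] * len(dims)
            ops[e_idx] = s_comp
            ops[2 + n_idx] = i_comp
            H += a * _embed(ops, dims)
    return H


def singlet_projector(system: RadicalPairSystem) -> np.ndarray:
    """Electron-singlet projector P̂S = ¼𝟙 − Ŝ_A·Ŝ_B on the full space.

    Idempotent, with trace M (one singlet level per nuclear configuration).
    """
    dim = system.dimension
    sa = _electron_vector_ops(system, "A")
    sb = _electron_vector_ops(system, "B")
    dot = sum(a @ b for a, b in zip(sa, sb))
    return 0.25 * np.eye(dim, dtype=complex) - dot


@dataclass(frozen=True)
class SpectralDecomposition:
    """Eigensystem of the spin Hamiltonian packaged for yield formulas.

    Attributes
    ----------
    field_uT : float
        Static field at which the decomposition was computed.
    omegas : ndarray
        Eigenfrequencies ω_m, rad s⁻¹ (ascending).
    weights : ndarray
        w_mn = |⟨m|P̂S|n⟩|², real symmetric, elementwise ≥ 0; the total
        Σ w_mn equals M because P̂S is a projector of rank M.
    M : int
        Number of nuclear spin configurations.
    """

    field_uT: float
    omegas: np.ndarray
    weights: np.ndarray
    M: int


def spectral_decomposition(
    system: RadicalPairSystem, B_uT: float
) -> SpectralDecomposition:
    """Diagonalise H(B) and form the singlet-projector weight matrix."""
    H = build_hamiltonian(system, B_uT)
    omegas, vecs = np.linalg.eigh(H)
    P = singlet_projector(system)
    p_eig = vecs.conj().T @ P @ vecs
    weights = np.abs(p_eig) ** 2
    return SpectralDecomposition(
        field_uT=float(B_uT),
        omegas=omegas,
        weights=weights,
        M=system.n_configurations,
    )


class SpectralCache:
    """Memoises spectral decompositions keyed on (system, field).

    The eigensystem depends only on the system and the static field; the
    kinetic parameters k and r enter the yield formula afterwards.  Sweeps
    over lifetimes and derivative stencils therefore reuse one
    decomposition per field value, which is the main performance lever of
    the lifetime-extremum searches.
    """

    def __init__(self) -> None:
        self._store: dict[tuple, SpectralDecomposition] = {}

    def get(self, system: RadicalPairSystem, B_uT: float) -> SpectralDecomposition:
        key = (system.fingerprint(), float(B_uT))
        spec = self._store.get(key)
        if spec is None:
            spec = spectral_decomposition(system, B_uT)
            self._store[key] = spec
        return spec

    def __len__(self) -> int:
        return len(self._store)


def triplet_probability(
    spec: SpectralDecomposition, t: float | np.ndarray, r: float = 0.0
) -> float | np.ndarray:
    """Probability that a singlet-born pair is in a triplet state at time t.

    The coherent part pT′(t) oscillates at the eigenfrequency differences;
    relaxation relaxes it toward the statistical ¾ with rate r:
    pT(t) = ¾ + (pT′(t) − ¾) e^(−rt).
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time t must be non-negative")
    if r < 0:
        raise ValueError("relaxation rate r must be non-negative")
    dw = (spec.omegas[:, None] - spec.omegas[None, :]).ravel()
    w = spec.weights.ravel()

    if t_arr.ndim == 0:
        pt_prime = 1.0 - float(np.cos(dw * float(t_arr)) @ w) / spec.M
        return 0.75 + (pt_prime - 0.75) * np.exp(-r * float(t_arr))

    flat = t_arr.ravel()
    sums = np.empty(flat.size)
    chunk = max(1, 4_000_000 // max(dw.size, 1))  # bound the cos buffer
    for i in range(0, flat.size, chunk):
        sums[i : i + chunk] = np.cos(np.outer(flat[i : i + chunk], dw)) @ w
    pt_prime = 1.0 - sums / spec.M
    out = 0.75 + (pt_prime - 0.75) * np.exp(-r * flat)
    return out.reshape(t_arr.shape)


def triplet_yield(spec: SpectralDecomposition, kin: ReactionKinetics) -> float:
    """Ultimate triplet yield ΦT for the exponential reaction model.

    Closed form of k∫₀^∞ pT(t) e^(−kt) dt; the m = n (Δω = 0) terms are
    included naturally by the Lorentzian factor.
    """
    k, r = kin.k, kin.r
    kr = k + r
    dw = spec.omegas[:, None] - spec.omegas[None, :]
    s = np.sum(spec.weights * (k * kr / (kr * kr + dw * dw)))
    return 0.75 + k / (4.0 * kr) - s / spec.M
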