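# Methods

## Model and assumptions

The simulated object is a spin-correlated radical pair born in the
electron-singlet state, e.g. the flavin–tryptophan pair formed by
photo-induced electron transfer in cryptochrome. The model keeps only
the interactions that drive singlet–triplet interconversion at
geomagnetic field strengths:

* electron Zeeman interaction with the external field, identical
  g = 2.0023 for both radicals (the Δg difference is negligible below
  millitesla fields);
* isotropic hyperfine couplings, expressed in field units (μT). The
  `FAD-TrpH` preset keeps the three largest nitrogen couplings (523,
  189, 322 μT, all spin-1); `FAD-Z` removes the couplings of the second
  radical entirely, the limiting case of a maximally asymmetric pair,
  which maximises low-field sensitivity.

Deliberately omitted: anisotropic hyperfine tensors (only relevant for
immobilised *and* aligned radicals), electron–electron exchange and
dipolar couplings (they suppress interconversion, so their omission
overestimates field effects), nuclear Zeeman terms (three orders of
magnitude below the electron terms), and any Liouville-space treatment
of spin-selective recombination. Both reaction channels share one rate
constant k (the exponential model) and relaxation is a single
phenomenological exponential toward the 1:3 singlet:triplet mixture
with rate r. These choices make the triplet yield available in closed
form from one Hermitian eigendecomposition, and they are all biased
toward *over*-estimating magnetic field effects, which is the point of
the exercise: the outputs are upper bounds.

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| B0 | static (geomagnetic) field | 50 μT | northern-European field strength |
| B1 | ELF peak amplitude | 1 μT | ≈0.7 μT rms, the epidemiological exposure threshold |
| ΔB0 | static offset | −1 μT | same magnitude as B1; negative so both effects usually share a sign |
| r | spin relaxation rate | 1e6 s⁻¹ | 1 μs coherence time, the optimistic end of what disordered biology permits |
| τ = 1/k | radical-pair lifetime | swept 1 ns – 1 ms | effects peak near 1 μs; the sweep brackets it by three decades each way |
| Δk/k, Δr/r | temperature sensitivity | 0.1 % per °C | corresponds to Ea ≈ 0.8 kJ mol⁻¹ (≈0.31 RT at 310 K) |

Fields and couplings are stored in μT and converted once to angular
frequencies through γe = g·μB/ħ with CODATA 2018 constants; the
published model states only g, and any modern constant set changes
results far below the printed two significant figures.

## Numerical procedure

**Spectral route.** H is assembled by Kronecker products in the fixed
order electron A ⊗ electron B ⊗ nuclei (declaration order, magnetic
quantum numbers descending) and diagonalised as a complex Hermitian
matrix (108×108 at most — no structure exploitation is warranted). The
weight matrix w_mn = |⟨m|P̂S|n⟩|² and the eigenfrequencies are cached per
(system, field): lifetime sweeps and derivative stencils reuse one
decomposition because k and r only enter the final Lorentzian sum.
Degenerate eigenvalues need no special handling — the yield formula is
smooth at Δω = 0.

**Derivatives.** ΦT′ and ΦT″ at B0 are central finite differences with
initial step 0.05 μT, halved until the two finest raw estimates agree to
1e-3 relative (with a 1e-9 absolute floor where the response is flat at
eigensolver noise level), and returned Richardson-extrapolated.
Perturbation-theoretic derivatives were rejected as over-engineering at
this matrix size. The step is a compromise: much smaller steps push the
second difference toward the ~1e-13 noise of the eigensolver, much
larger ones pick up the curvature variation of the yield curve, whose
features vary on the 10 μT scale.

**Phase average.** The quadrature route to the ELF effect integrates
ΦT(B0 + B1 cos α) over α ∈ (0, π) by Gauss–Legendre quadrature
(20 nodes, doubled until the effect changes by <1e-4 relative). It
makes no small-B1 assumption and validates the Taylor route; the Taylor
route is restricted to B1 ≤ 0.2·B0 (likewise |ΔB0| ≤ 0.2·B0 for the
linearised static-offset effect).

**Extremisation.** "Maximum effect" means the signed value of largest
magnitude over τ ∈ [1 ns, 1 ms] at fixed r, located on a log grid of 25
points per decade and refined by golden-section search in log τ to 1e-3
relative. The ELF and static-offset extrema are found independently
(their τ* generally differ); their ratio Ω = mfeGMFmax/mfeELFmax is a
ratio of signed extrema. Printed tables round to two significant
figures; result objects keep full precision.

**Oracles.** Two brute-force routes exist purely for validation: direct
unitary propagation of ρ(0) = P̂S/M by matrix exponentials (checks the
eigenbasis cosine sum), and composite Gauss–Legendre time quadrature of
k·pT(t)e^(−kt) truncated at 40/k, with the panel count doubled to
convergence (checks the analytic Lorentzian sum; the truncated tail is
below e⁻⁴⁰). The tests require agreement to 1e-10 (probabilities,
absolute) and 1e-6 (yields, relative).

## Test systems

Property tests run on randomly generated small pairs (1–3 nuclei, spin
½ or 1, couplings 50–600 μT, random electron assignment, seeded rng).
These emulate the *structure* of realistic radical pairs — a handful of
dominant isotropic couplings of hundreds of μT — but not their full
complexity: real radicals carry many small couplings, anisotropy, and
correlated relaxation pathways. Passing tests therefore certify the
spin-dynamics arithmetic and the scaling laws, not quantitative
predictions for any real molecule beyond the bounded model itself.

## Design choices on open points

* **Sign structure at fast relaxation.** At r = 1e6 s⁻¹ both effects
  are negative over the lifetimes where the low-field effect is
  prominent. At r = 1e7 s⁻¹ the curvature of ΦT(B0) at 50 μT turns
  positive, flipping the ELF effect's sign across that window, while
  the gradient-driven static-offset effect turns positive only at short
  lifetimes (its largest-magnitude value can remain negative). The
  tests assert exactly this computed structure rather than a blanket
  sign statement.
* **Random-orientation averaging.** The effective amplitude of a
  randomly oriented ELF field is computed under two conventions:
  ⟨cos θ⟩ with θ uniform on (0, π/2) (factor 2/π ≈ 0.64, the default,
  matching the 49.36–50.64 μT range quoted for a 1 μT field on 50 μT)
  and the solid-angle average ⟨|cos θ|⟩ = ½. Both are reported; the
  parallel-field assumption overestimates the quadratic ELF effect by
  f⁻² (≈2.5 or 4).
* **37 °C is taken as 310.15 K**; the activation-energy estimate is
  insensitive to the convention at the printed precision.
* **Figure-sweep grids.** The static-field sweep uses lifetimes
  {30 ns, 100 ns, 300 ns, 1 μs, 3 μs, 10 μs, 100 μs}; lifetime sweeps
  default to 61 log-spaced points over 1 ns–1 ms, and the acceptance
  extremisation uses the full 25-points-per-decade scan. These grids
  resolve every feature the coarser printed curves show.

## Known limitations

The 50/60 Hz field is never propagated as a time-dependent Hamiltonian;
the static-phase approximation is adopted, not tested dynamically (it
fails only for lifetimes approaching the 20 ms ELF period, where
relaxation has long since destroyed coherence). Triplet-born and
F-pair initial states, asymmetric or semi-spin-selective recombination,
and amplification schemes (superparamagnetic boosts beyond the
thermodynamic ratio mB/kBT, scavenger or feedback kinetics) are out of
scope; where such mechanisms matter they rescale both field effects
similarly and move their ratio by tens of percent, not orders of
magnitude.
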