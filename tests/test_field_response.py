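"""Field sweeps, yield derivatives, ELF/GMF effects and their extrema."""

import numpy as np
import pytest

from radpair import (
    DegenerateExtremumError,
    FieldProtocol,
    ReactionKinetics,
    SpectralCache,
    SweepResult,
    equivalent_static_change,
    lifetime_extremum,
    mfe_elf_quadrature,
    mfe_elf_taylor,
    mfe_gmf,
    omega_ratio,
    phi_derivative,
    phi_vs_field,
    spectral_decomposition,
    triplet_yield,
)

PROTO = FieldProtocol(B0_uT=50.0, B1_uT=1.0, dB0_uT=-1.0)


class TestPhiVsField:
    def test_low_field_effect_shape(self, fad_trph):
        """At τ = 1 μs the yield curve is bi-phasic: a low-field rise below
        1 mT followed by a larger high-field decrease."""
        kin = ReactionKinetics.from_lifetime(1e-6, 1e6)
        sweep = phi_vs_field(fad_trph, kin, [0.0, 500.0, 5000.0])
        phi0, phi_lfe, phi_high = sweep.values
        assert phi_lfe > phi0
        assert phi_high < phi0

    def test_long_lifetime_field_independent(self, fad_trph):
        """At τ = 100 μs relaxation flattens the field response."""
        kin = ReactionKinetics.from_lifetime(1e-4, 1e6)
        grid = np.linspace(0.0, 5000.0, 11)
        sweep = phi_vs_field(fad_trph, kin, grid)
        assert sweep.values.max() - sweep.values.min() < 0.01

    def test_empty_grid_rejected(self, fad_z):
        with pytest.raises(ValueError):
            phi_vs_field(fad_z, ReactionKinetics(1e6, 1e6), [])


class TestPhiDerivative:
    def test_flat_for_bare_pair(self, bare_pair):
        kin = ReactionKinetics(1e6, 1e6)
        assert abs(phi_derivative(bare_pair, kin, 50.0, 1)) < 1e-12
        assert abs(phi_derivative(bare_pair, kin, 50.0, 2)) < 1e-12

    def test_positive_gradient_at_geomagnetic_field(self, fad_trph):
        """The low-field rise makes dΦT/dB positive at 50 μT for τ = 1 μs."""
        kin = ReactionKinetics.from_lifetime(1e-6, 1e6)
        assert phi_derivative(fad_trph, kin, 50.0, 1) > 0

    @pytest.mark.parametrize("order", [1, 2])
    def test_against_local_quadratic_fit(self, fad_z, order):
        """Independent oracle: a quadratic fit of ΦT over ±0.2 μT."""
        kin = ReactionKinetics.from_lifetime(1e-6, 1e6)
        b = 50.0 + np.linspace(-0.2, 0.2, 5)
        phis = [triplet_yield(spectral_decomposition(fad_z, bi), kin) for bi in b]
        coeffs = np.polyfit(b - 50.0, phis, 2)
        expected = coeffs[1] if order == 1 else 2 * coeffs[0]
        assert phi_derivative(fad_z, kin, 50.0, order) == pytest.approx(
            expected, rel=1e-2
        )

    def test_invalid_order(self, fad_z):
        with pytest.raises(ValueError):
            phi_derivative(fad_z, ReactionKinetics(1e6), 50.0, 3)


class TestMfeElf:
    def test_zero_amplitude_gives_zero(self, fad_z):
        kin = ReactionKinetics.from_lifetime(1e-6, 1e6)
        proto = FieldProtocol(50.0, 0.0, -1.0)
        assert mfe_elf_taylor(fad_z, kin, proto).value == 0.0
        assert mfe_elf_quadrature(fad_z, kin, proto).value == 0.0

    def test_taylor_bound_enforced(self, fad_z):
        kin = ReactionKinetics.from_lifetime(1e-6, 1e6)
        with pytest.raises(ValueError):
            mfe_elf_taylor(fad_z, kin, FieldProtocol(50.0, 20.0, -1.0))

    @pytest.mark.parametrize("tau", [1e-7, 3e-7, 1e-6, 3e-6, 1e-5])
    def test_taylor_agrees_with_quadrature(self, fad_trph, tau):
        """At B1/B0 = 0.02 the curvature formula matches explicit phase
        averaging to 5%."""
        kin = ReactionKinetics.from_lifetime(tau, 1e6)
        cache = SpectralCache()
        t = mfe_elf_taylor(fad_trph, kin, PROTO, cache=cache)
        q = mfe_elf_quadrature(fad_trph, kin, PROTO, cache=cache)
        assert t.value == pytest.approx(q.value, rel=0.05)

    def test_quadratic_scaling_in_amplitude(self, fad_z):
        """Doubling B1 quadruples the effect (verified by quadrature, which
        does not assume the scaling)."""
        kin = ReactionKinetics.from_lifetime(1e-6, 1e6)
        cache = SpectralCache()
        m1 = mfe_elf_quadrature(
            fad_z, kin, FieldProtocol(50.0, 1.0, -1.0), cache=cache
        )
        m2 = mfe_elf_quadrature(
            fad_z, kin, FieldProtocol(50.0, 2.0, -1.0), cache=cache
        )
        assert m2.value / m1.value == pytest.approx(4.0, rel=0.05)

    def test_ppm_property(self, fad_z):
        kin = ReactionKinetics.from_lifetime(1e-6, 1e6)
        res = mfe_elf_taylor(fad_z, kin, PROTO)
        assert res.ppm == res.value * 1e6


class TestMfeGmf:
    def test_zero_offset_gives_zero(self, fad_z):
        kin = ReactionKinetics.from_lifetime(1e-6, 1e6)
        proto = FieldProtocol(50.0, 1.0, 0.0)
        for method in ("exact_difference", "linear"):
            assert mfe_gmf(fad_z, kin, proto, method).value == 0.0

    def test_linear_matches_exact_difference(self, fad_trph):
        """For |ΔB0| = 0.1 μT the gradient formula and the exact yield
        difference agree to 2%."""
        kin = ReactionKinetics.from_lifetime(1e-6, 1e6)
        proto = FieldProtocol(50.0, 1.0, -0.1)
        cache = SpectralCache()
        lin = mfe_gmf(fad_trph, kin, proto, "linear", cache=cache)
        exact = mfe_gmf(fad_trph, kin, proto, "exact_difference", cache=cache)
        assert lin.value == pytest.approx(exact.value, rel=0.02)

    def test_linear_scaling_in_offset(self, fad_z):
        kin = ReactionKinetics.from_lifetime(1e-6, 1e6)
        cache = SpectralCache()
        m1 = mfe_gmf(fad_z, kin, FieldProtocol(50.0, 1.0, -0.5), cache=cache)
        m2 = mfe_gmf(fad_z, kin, FieldProtocol(50.0, 1.0, -1.0), cache=cache)
        assert m2.value / m1.value == pytest.approx(2.0, rel=1e-6)


class TestLifetimeExtremum:
    def test_bare_pair_is_degenerate(self, bare_pair):
        for mode in ("elf", "gmf"):
            with pytest.raises(DegenerateExtremumError):
                lifetime_extremum(bare_pair, 1e6, PROTO, mode)

    def test_sign_structure_reference_relaxation(self, fad_trph, fad_z):
        """At r = 1e6 s⁻¹ both effects are negative over the lifetimes
        where the low field effect is prominent (0.3–10 μs), because the
        yield curve at 50 μT has positive gradient and negative curvature;
        the extrema over the full range are negative too."""
        for system in (fad_trph, fad_z):
            cache = SpectralCache()
            for tau in (3e-7, 1e-6, 1e-5):
                kin = ReactionKinetics.from_lifetime(tau, 1e6)
                assert mfe_elf_taylor(system, kin, PROTO, cache=cache).value < 0
                assert mfe_gmf(system, kin, PROTO, cache=cache).value < 0
            _, elf = lifetime_extremum(system, 1e6, PROTO, "elf", cache=cache)
            _, gmf = lifetime_extremum(system, 1e6, PROTO, "gmf", cache=cache)
            assert elf.value < 0 and gmf.value < 0

    def test_sign_change_at_fast_relaxation(self, fad_trph):
        """At r = 1e7 s⁻¹ the yield curvature at 50 μT turns positive, so
        mfeELF flips sign over the same lifetime window, and mfeGMF also
        attains positive values (at short lifetimes)."""
        cache = SpectralCache()
        for tau in (3e-7, 1e-6, 1e-5):
            kin = ReactionKinetics.from_lifetime(tau, 1e7)
            assert mfe_elf_taylor(fad_trph, kin, PROTO, cache=cache).value > 0
        taus = np.logspace(-8.0, -5.0, 25)
        gmf_vals = [
            mfe_gmf(
                fad_trph, ReactionKinetics.from_lifetime(t, 1e7), PROTO, cache=cache
            ).value
            for t in taus
        ]
        assert max(gmf_vals) > 0

    def test_relaxation_attenuation(self, fad_trph):
        """Tenfold faster relaxation shrinks both extrema by roughly an
        order of magnitude while Ω moves by less than a factor of 2."""
        results = {}
        for r in (1e6, 1e7):
            cache = SpectralCache()
            _, elf = lifetime_extremum(fad_trph, r, PROTO, "elf", cache=cache)
            _, gmf = lifetime_extremum(fad_trph, r, PROTO, "gmf", cache=cache)
            results[r] = (elf.value, gmf.value)
        elf_ratio = abs(results[1e7][0] / results[1e6][0])
        gmf_ratio = abs(results[1e7][1] / results[1e6][1])
        assert 0.02 < elf_ratio < 0.3
        assert 0.02 < gmf_ratio < 0.3
        omega_slow = results[1e6][1] / results[1e6][0]
        omega_fast = results[1e7][1] / results[1e7][0]
        assert 0.5 < abs(omega_fast / omega_slow) < 2.0

    def test_static_field_dependence_of_elf_maximum(self, fad_trph):
        """A weaker static field gives a larger ELF effect (and vice
        versa): |mfeELFmax| at 25 μT > 50 μT > 65 μT."""
        mags = {}
        for b0 in (25.0, 50.0, 65.0):
            proto = FieldProtocol(b0, 1.0, -1.0)
            _, res = lifetime_extremum(fad_trph, 1e6, proto, "elf")
            mags[b0] = abs(res.value)
        assert mags[25.0] > mags[50.0] > mags[65.0]

    def test_invalid_range(self, fad_z):
        with pytest.raises(ValueError):
            lifetime_extremum(fad_z, 1e6, PROTO, "elf", tau_range=(1e-3, 1e-9))


class TestOmegaRatio:
    def test_inverse_square_scaling_in_b1(self, fad_z):
        """Ω ∝ 1/B1² at fixed ΔB0 (GMF extremum is B1-independent, ELF
        extremum quadratic in B1)."""
        omega1 = omega_ratio(fad_z, 1e6, B1_uT=1.0)
        omega2 = omega_ratio(fad_z, 1e6, B1_uT=2.0)
        assert omega2 / omega1 == pytest.approx(0.25, rel=0.05)

    def test_equivalent_static_change_arithmetic(self):
        assert equivalent_static_change(1000.0, 1.0) == pytest.approx(-1.0)
        with pytest.raises(ZeroDivisionError):
            equivalent_static_change(0.0, 1.0)


class TestSweepResult:
    def test_monotone_axis_enforced(self):
        with pytest.raises(ValueError):
            SweepResult("x", [1.0, 1.0, 2.0], [0.0, 0.0, 0.0])

    def test_csv_roundtrip_is_exact(self, tmp_path):
        sweep = SweepResult(
            "tau_s",
            np.logspace(-9, -3, 7),
            np.array([-1.2e-6, 3.4e-7, 0.0, -5.5e-9, 1.0 / 3.0, 2.0, -7.1e2]),
            metadata={"system": "FAD-Z", "r_per_s": 1e6},
        )
        path = tmp_path / "sweep.csv"
        sweep.to_csv(path)
        back = SweepResult.from_csv(path)
        assert back.axis_name == "tau_s"
        np.testing.assert_array_equal(back.axis_values, sweep.axis_values)
        np.testing.assert_array_equal(back.values, sweep.values)
        assert back.metadata["system"] == "FAD-Z"
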