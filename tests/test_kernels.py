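import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmsse import (
    CorrelationKernel,
    DimerSpec,
    ExponentialFilter,
    MarkDistribution,
    ModelSpec,
    PoissonBathSpec,
    SpectralDensitySpec,
    ThermalSpec,
    filtered_kernel_from_phi,
    gaussian_kernel,
    memory_coefficients,
    poisson_kernel,
    regime_controls,
    second_jump_moment,
    spectral_density,
    thermal_occupation,
    variance_match,
)
from _oracles import riemann_kernel_value


class TestSpectralDensity:
    def test_vanishes_at_zero(self, canon_bath):
        assert spectral_density(0.0, canon_bath) == 0.0

    def test_single_band_peak_value(self):
        """At the band centre J(w_i) = gamma w_i / Gamma."""
        spec = SpectralDensitySpec(mode_freqs=[0.1], gamma=0.01, linewidth=0.005)
        assert spectral_density(0.1, spec) == pytest.approx(0.01 * 0.1 / 0.005)
        assert spectral_density(0.1, spec) == pytest.approx(0.2)

    def test_nonnegative_on_grid(self, canon_bath):
        w = np.linspace(0.0, 2.0, 4001)
        assert np.all(spectral_density(w, canon_bath) >= 0.0)


class TestThermalOccupation:
    def test_canonical_value(self, canon_thermal):
        # the quantized-mode regime: n_th ~ 2.6e-3 at 0.1487 eV / 25 meV
        assert thermal_occupation(0.1487, canon_thermal) == pytest.approx(2.6e-3, abs=5e-5)

    def test_unit_occupation_at_ln2(self):
        assert thermal_occupation(0.025 * np.log(2.0), ThermalSpec(0.025)) == pytest.approx(1.0)

    def test_zero_temperature_convention(self):
        assert thermal_occupation(0.1, ThermalSpec(0.0)) == 0.0


class TestGaussianKernel:
    def test_zero_coupling_gives_zero_kernel(self, canon_thermal):
        spec = SpectralDensitySpec(mode_freqs=[0.1], gamma=0.0, linewidth=0.005)
        k = gaussian_kernel(np.arange(0.0, 10.0), spec, canon_thermal)
        assert np.all(k.values == 0.0)

    def test_zero_temperature_limit_forms_agree(self, canon_bath):
        """At kbt = 0 coth -> 1 and both integrand forms reduce to
        int J e^{-iw tau} dw."""
        tau = np.array([0.0, 5.0, 40.0])
        k_printed = gaussian_kernel(tau, canon_bath, ThermalSpec(0.0), form="full_coth")
        k_standard = gaussian_kernel(tau, canon_bath, ThermalSpec(0.0), form="standard")
        assert np.allclose(k_printed.values, k_standard.values, rtol=1e-9)

    def test_against_riemann_oracle(self, canon_bath, canon_thermal):
        """Adaptive Simpson quadrature agrees with an independent
        brute-force Riemann sum to 1e-6 relative at several lags."""
        tau = np.array([0.0, 1.0, 25.0])
        k = gaussian_kernel(tau, canon_bath, canon_thermal)
        cutoff = 10.0 * max(canon_bath.mode_freqs)
        for i, lag in enumerate(tau):
            ref = riemann_kernel_value(
                lag,
                canon_bath.mode_freqs,
                canon_bath.gamma,
                canon_bath.linewidth,
                canon_thermal.kbt,
                cutoff,
            )
            assert abs(k.values[i] - ref) <= 1e-6 * abs(ref)

    def test_alpha0_real_positive_and_symmetry(self, canon_bath, canon_thermal):
        tau = np.arange(0.0, 101.0)
        k = gaussian_kernel(tau, canon_bath, canon_thermal)
        assert k.at_zero > 0.0
        assert k.values[0].imag == 0.0
        # stationary Hermitian symmetry through the interpolator
        lags = np.array([3.7, 12.2, 55.0])
        assert np.allclose(k.at(-lags), np.conj(k.at(lags)))


class TestPoissonKernel:
    def test_amplitude_at_zero_lag(self):
        spec = PoissonBathSpec(rate=0.01, filter_kappa=0.005, filter_omega=0.1, amplitude=0.01)
        k = poisson_kernel(np.array([0.0, 10.0]), spec)
        assert k.at_zero == pytest.approx(0.01)

    def test_pure_exponential_decay(self):
        spec = PoissonBathSpec(rate=0.01, filter_kappa=0.25, filter_omega=0.0, amplitude=1.0)
        k = poisson_kernel(np.array([0.0, 4.0]), spec)
        assert k.values[1].real == pytest.approx(np.exp(-1.0))

    def test_closed_form_value(self):
        spec = PoissonBathSpec(rate=0.01, filter_kappa=0.005, filter_omega=0.1, amplitude=0.01)
        k = poisson_kernel(np.array([0.0, 100.0]), spec)
        assert k.values[1].real == pytest.approx(0.01 * np.exp(-0.5) * np.cos(10.0), abs=1e-15)

    def test_envelope_bound(self):
        spec = PoissonBathSpec(rate=0.01, filter_kappa=0.01, filter_omega=0.3, amplitude=0.5)
        tau = np.linspace(0.0, 400.0, 801)
        k = poisson_kernel(tau, spec)
        assert np.all(np.abs(k.values) <= 0.5 * np.exp(-0.01 * tau) + 1e-12)


class TestFilteredKernel:
    def test_zero_rate_gives_zero(self):
        phi = ExponentialFilter(kappa=0.02)
        k = filtered_kernel_from_phi(np.array([0.0, 5.0]), phi, 0.0)
        assert np.all(k.values == 0.0)

    def test_exponential_case_closed_form(self):
        """phi = e^{-ku}: alpha(0) = lam E[a^2] / 2k, decay e^{-k tau};
        quadrature vs closed form to 1e-8."""
        kappa, jump_moment = 0.05, 0.3
        phi = ExponentialFilter(kappa=kappa)
        tau = np.array([0.0, 5.0, 20.0, 60.0])
        k = filtered_kernel_from_phi(tau, phi, jump_moment)
        ref = jump_moment * np.exp(-kappa * tau) / (2.0 * kappa)
        assert np.abs(k.values - ref).max() < 1e-8

    def test_modulated_filter_matches_analytic_self_correlation(self):
        filt = ExponentialFilter(kappa=0.02, omega=0.15)
        tau = np.array([0.0, 3.0, 17.0])
        k = filtered_kernel_from_phi(tau, filt, 1.7)
        ref = filt.self_correlation(tau, weight=1.7)
        assert np.abs(k.values - ref).max() < 1e-8 * np.abs(ref).max()

    def test_variance_matched_poisson_kernel_equals_filtered(self):
        """With w_P = 0 the ansatz kernel and the filtered quadrature agree
        pointwise to 1e-8 after variance matching."""
        spec = PoissonBathSpec(
            rate=0.02,
            marks=MarkDistribution("two_point", 1.0),
            filter_kappa=0.01,
            filter_omega=0.0,
        )
        matched = variance_match(0.04, spec)
        tau = np.linspace(0.0, 300.0, 31)
        ansatz = poisson_kernel(tau, matched)
        filtered = filtered_kernel_from_phi(
            tau, ExponentialFilter(kappa=0.01), second_jump_moment(matched)
        )
        assert np.abs(ansatz.values - filtered.values).max() < 1e-8


class TestSecondJumpMoment:
    def test_zero_rate(self):
        assert second_jump_moment(PoissonBathSpec(rate=0.0, filter_kappa=0.01)) == 0.0

    @pytest.mark.parametrize(
        "family, scale, expected_m2",
        [("fixed", 0.7, 0.49), ("two_point", 0.7, 0.49), ("gaussian", 0.5, 0.25)],
    )
    def test_families(self, family, scale, expected_m2):
        spec = PoissonBathSpec(
            rate=0.2, marks=MarkDistribution(family, scale), filter_kappa=0.01
        )
        assert second_jump_moment(spec) == pytest.approx(0.2 * expected_m2)

    def test_gaussian_fourth_moment(self):
        assert MarkDistribution("gaussian", 2.0).moment(4) == pytest.approx(3 * 16.0)


class TestMemoryCoefficients:
    def test_zero_at_origin(self, canon_bath, canon_thermal):
        t = np.arange(0.0, 51.0) * 0.5
        k = gaussian_kernel(t, canon_bath, canon_thermal)
        co = memory_coefficients(k, t)
        assert co.g0[0] == 0.0 and co.g1[0] == 0.0

    def test_exponential_kernel_closed_forms(self):
        """g0 = A(1-e^{-kt})/k and g1 = A[1-(1+kt)e^{-kt}]/k^2 to 1e-8 at
        every grid point."""
        a, kappa = 0.3, 0.05
        t = np.arange(0.0, 2001.0) * 0.1
        kern = CorrelationKernel(t, (a * np.exp(-kappa * t)).astype(complex))
        co = memory_coefficients(kern, t, order=1)
        g0_ref = a * (1.0 - np.exp(-kappa * t)) / kappa
        g1_ref = a * (1.0 - (1.0 + kappa * t) * np.exp(-kappa * t)) / kappa**2
        assert np.abs(co.g0 - g0_ref).max() < 1e-8
        assert np.abs(co.g1 - g1_ref).max() < 1e-8

    def test_markovian_limit_g1_over_g0_vanishes(self):
        """kappa -> infinity at fixed integrated weight: g1/g0 -> 0 (only
        the zeroth-order memory term survives)."""
        t = np.arange(0.0, 501.0) * 0.02
        ratios = []
        for kappa in (0.5, 2.0, 8.0):
            kern = CorrelationKernel(t, (kappa * np.exp(-kappa * t)).astype(complex))
            co = memory_coefficients(kern, t)
            ratios.append(abs(co.g1[-1] / co.g0[-1]))
        assert ratios[0] > ratios[1] > ratios[2]
        assert ratios[2] < 0.2 / 0.5

    def test_g2_double_integral_against_slow_oracle(self):
        """Nested g2 agrees with a direct O(n^2) double Riemann sum."""
        a, kappa = 0.2, 0.1
        t = np.arange(0.0, 201.0) * 0.05
        kern = CorrelationKernel(t, (a * np.exp(-kappa * t)).astype(complex))
        co = memory_coefficients(kern, t, order=2)

        def alpha(u):
            return a * np.exp(-kappa * np.abs(u))

        m = t.size - 1
        s = t
        inner = np.array(
            [np.trapezoid(alpha(si - s[: i + 1]), s[: i + 1]) for i, si in enumerate(s)]
        )
        ref = np.trapezoid((t[m] - s) * alpha(t[m] - s) * inner, s)
        assert co.g2[m] == pytest.approx(ref, rel=1e-5)

    def test_coarse_grid_rejected_for_g2(self):
        t = np.arange(0.0, 4.0)
        kern = CorrelationKernel(t, np.exp(-t).astype(complex))
        with pytest.raises(ValueError):
            memory_coefficients(kern, t, order=2)


class TestVarianceMatch:
    def test_mark_scale_inversion(self):
        """E[a^2] = 2 kappa V / lambda_p for the exponential filter."""
        spec = PoissonBathSpec(rate=0.05, filter_kappa=0.01, filter_omega=0.0)
        matched = variance_match(0.2, spec)
        assert matched.marks.moment(2) == pytest.approx(2 * 0.01 * 0.2 / 0.05)
        assert matched.a0 == pytest.approx(0.2)

    def test_doubling_rate_halves_second_moment(self):
        spec = PoissonBathSpec(rate=0.05, filter_kappa=0.01)
        m1 = variance_match(0.2, spec).marks.moment(2)
        m2 = variance_match(0.2, PoissonBathSpec(rate=0.1, filter_kappa=0.01)).marks.moment(2)
        assert m2 == pytest.approx(m1 / 2.0)

    @given(
        v=st.floats(1e-6, 10.0),
        kappa=st.floats(1e-4, 1.0),
        rate=st.floats(1e-6, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_idempotent_and_preserves_variance(self, v, kappa, rate):
        spec = PoissonBathSpec(rate=rate, filter_kappa=kappa)
        once = variance_match(v, spec)
        twice = variance_match(v, once)
        assert twice == once
        k = poisson_kernel(np.array([0.0]), once)
        assert abs(k.at_zero - v) <= 1e-12 * max(1.0, v)

    def test_zero_rate_cannot_match(self):
        with pytest.raises(ValueError):
            variance_match(0.1, PoissonBathSpec(rate=0.0, filter_kappa=0.01))


class TestRegimeControls:
    def test_canonical_numbers(self, canon_dimer):
        """Gamma = 5 meV gives tau_c = 200; with Delta = 0.1 eV the
        non-Markovianity measure is ~36 ( >> 1 )."""
        model = ModelSpec(dimer=canon_dimer)
        rc = regime_controls(model, 0.005, rate=0.05)
        assert rc.tau_c == pytest.approx(200.0)
        assert rc.tau_sys == pytest.approx(5.58, abs=5e-3)
        assert rc.eta_nm == pytest.approx(35.8, abs=0.1)
        assert rc.lam == pytest.approx(10.0)
        assert rc.eta_nm == pytest.approx(rc.omega_sys * rc.tau_c)

    def test_invalid_width(self, canon_dimer):
        with pytest.raises(ValueError):
            regime_controls(ModelSpec(dimer=canon_dimer), 0.0)


class TestCorrelationKernelType:
    def test_rejects_negative_variance(self):
        with pytest.raises(ValueError):
            CorrelationKernel(np.array([0.0, 1.0]), np.array([-1.0, 0.0], dtype=complex))

    def test_rejects_complex_origin(self):
        with pytest.raises(ValueError):
            CorrelationKernel(np.array([0.0, 1.0]), np.array([1.0 + 1.0j, 0.0]))

    def test_csv_roundtrip_frame(self, canon_bath, canon_thermal):
        tau = np.arange(0.0, 11.0)
        k = gaussian_kernel(tau, canon_bath, canon_thermal)
        frame = k.to_frame()
        assert list(frame.columns) == ["tau", "re", "im"]
        assert np.allclose(frame["re"].to_numpy() + 1j * frame["im"].to_numpy(), k.values)
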