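import numpy as np
import pytest

from nmsse import (
    CorrelationKernel,
    DimerSpec,
    ExponentialFilter,
    GaussianPathFactory,
    MarkDistribution,
    ModelSpec,
    PoissonBathSpec,
    VibronicSpec,
    empirical_cumulant,
    filter_and_compensate,
    kick_unitary,
    sample_events,
    sample_gaussian_path,
    second_jump_moment,
)
from nmsse.noise import KickOperator, compensated_jump_path, spawn_seeds


@pytest.fixture(scope="module")
def exp_kernel():
    tau = np.arange(0.0, 201.0)
    return CorrelationKernel(tau, (0.5 * np.exp(-0.05 * tau) * np.exp(-1j * 0.1 * tau)))


class TestGaussianPaths:
    def test_zero_kernel_gives_zero_path(self):
        tau = np.arange(0.0, 50.0)
        kern = CorrelationKernel(tau, np.zeros_like(tau, dtype=complex))
        path = sample_gaussian_path(kern, tau, seed=3)
        assert np.all(path.z == 0.0)

    def test_seeded_reproducibility(self, exp_kernel):
        t = exp_kernel.tau_grid
        a = sample_gaussian_path(exp_kernel, t, seed=42)
        b = sample_gaussian_path(exp_kernel, t, seed=42)
        c = sample_gaussian_path(exp_kernel, t, seed=43)
        assert np.array_equal(a.z, b.z)
        assert not np.array_equal(a.z, c.z)

    def test_ensemble_mean_and_covariance(self, exp_kernel):
        """n = 5000 paths: mean within 3 SE of zero everywhere; covariance
        at lags {0, tau_c/2, tau_c} within 5% of the kernel; vanishing
        pseudo-covariance (circular symmetry)."""
        t = exp_kernel.tau_grid
        fac = GaussianPathFactory(exp_kernel, t)
        z = fac.sample(5000, 2026)
        se = np.sqrt(exp_kernel.at_zero / len(z))
        assert np.abs(z.mean(axis=0)).max() < 3.0 * se * np.sqrt(2.0)
        tau_c = 20  # 1/0.05 in grid units
        for lag in (0, tau_c // 2, tau_c):
            emp = (z[:, lag:] * z[:, : t.size - lag].conj()).mean()
            ref = exp_kernel.at(float(lag))
            assert abs(emp - ref) <= 0.05 * abs(exp_kernel.at_zero)
        pseudo = (z[:, 1:] * z[:, :-1]).mean()
        assert abs(pseudo) < 0.05 * exp_kernel.at_zero

    def test_indefinite_kernel_rejected(self):
        tau = np.arange(0.0, 3.0)
        bad = CorrelationKernel(tau, np.array([0.1, 0.9, 0.0], dtype=complex))
        with pytest.raises(ValueError, match="indefinite"):
            GaussianPathFactory(bad, tau)


class TestEventStream:
    def test_zero_rate_empty(self):
        spec = PoissonBathSpec(rate=0.0, filter_kappa=0.01)
        assert len(sample_events(spec, 1000.0, seed=1)) == 0

    def test_poisson_count_statistics(self):
        """Mean and variance of the event count match lambda_p * T."""
        spec = PoissonBathSpec(rate=0.05, filter_kappa=0.01)
        t_max, reps = 100.0, 2000
        counts = np.array([len(sample_events(spec, t_max, seed=s)) for s in range(reps)])
        expected = 0.05 * t_max
        se = np.sqrt(expected / reps)
        assert abs(counts.mean() - expected) < 3.0 * se
        var_se = expected * np.sqrt(2.0 / reps) * 2.0  # loose bound on var-of-var
        assert abs(counts.var() - expected) < 3.0 * var_se

    def test_reproducible_and_sorted(self):
        spec = PoissonBathSpec(rate=0.1, marks=MarkDistribution("gaussian", 1.0), filter_kappa=0.01)
        a = sample_events(spec, 500.0, seed=9)
        b = sample_events(spec, 500.0, seed=9)
        assert np.array_equal(a.times, b.times) and np.array_equal(a.marks, b.marks)
        assert np.all(np.diff(a.times) > 0)


class TestFilterAndCompensate:
    def test_single_event_response(self):
        """One event at t1 with mark a1: z(t) = a1 e^{-k(t-t1)} for t >= t1."""
        from nmsse.noise import EventStream

        t = np.arange(0.0, 100.0)
        ev = EventStream(times=np.array([20.0]), marks=np.array([0.8]), rate=0.0)
        path = filter_and_compensate(ev, ExponentialFilter(kappa=0.1), t)
        expected = np.where(t >= 20.0, 0.8 * np.exp(-0.1 * (t - 20.0)), 0.0)
        assert np.abs(path.z.real - expected).max() < 1e-12

    def test_no_events_zero_mean_marks(self):
        from nmsse.noise import EventStream

        t = np.arange(0.0, 10.0)
        ev = EventStream(times=np.array([]), marks=np.array([]), rate=0.3)
        path = filter_and_compensate(ev, ExponentialFilter(kappa=0.1), t)
        assert np.all(path.z == 0.0)

    def test_compensation_removes_mean(self):
        """Fixed (positive-mean) marks: compensated paths average to zero
        within 3 SE after the filter transient."""
        spec = PoissonBathSpec(
            rate=0.05, marks=MarkDistribution("fixed", 1.0), filter_kappa=0.02
        )
        filt = ExponentialFilter(kappa=0.02)
        t = np.arange(0.0, 601.0)
        n = 1500
        acc = np.zeros(t.size)
        for s in range(n):
            ev = sample_events(spec, t[-1], seed=s)
            acc += filter_and_compensate(ev, filt, t, mark_mean=1.0).z.real
        mean = acc / n
        tail = t > 5.0 / 0.02
        std_stat = np.sqrt(second_jump_moment(spec) / (2 * 0.02))
        assert np.abs(mean[tail]).max() < 3.5 * std_stat / np.sqrt(n)

    def test_stationary_variance_matches_kernel(self):
        """Long-run variance = lambda_p E[a^2] / (2 kappa) within 5%."""
        kappa = 0.02
        spec = PoissonBathSpec(
            rate=0.05, marks=MarkDistribution("two_point", 1.3), filter_kappa=kappa
        )
        filt = ExponentialFilter(kappa=kappa)
        t = np.arange(0.0, 801.0)
        samples = []
        for s in range(800):
            ev = sample_events(spec, t[-1], seed=10_000 + s)
            z = filter_and_compensate(ev, filt, t).z.real
            samples.append(z[t > 5.0 / kappa])
        var = np.concatenate(samples).var()
        target = second_jump_moment(spec) / (2.0 * kappa)
        assert var == pytest.approx(target, rel=0.05)


class TestCumulants:
    def _paths(self, spec, t, n, seed0=0):
        return [
            compensated_jump_path(
                sample_events(spec, t[-1], seed=seed0 + s), t, mark_mean=spec.marks.moment(1)
            )
            for s in range(n)
        ]

    def test_gaussian_paths_have_zero_excess_kurtosis(self, exp_kernel):
        t = exp_kernel.tau_grid
        fac = GaussianPathFactory(exp_kernel, t)
        z = fac.sample(1200, 7)
        from nmsse.noise import NoisePath

        paths = [NoisePath(t, zi) for zi in z]
        k4 = empirical_cumulant(paths, order=4)
        k2 = empirical_cumulant(paths, order=2)
        assert abs(k4.value) < 3.0 * k4.se + 1e-3 * k2.value**2

    def test_third_cumulant_of_fixed_marks(self):
        """kappa_3 of the compensated increments = lambda_p a0^3 dt."""
        dt, a0, rate = 1.0, 1.0, 0.02
        spec = PoissonBathSpec(rate=rate, marks=MarkDistribution("fixed", a0), filter_kappa=0.01)
        t = np.arange(0.0, 501.0) * dt
        paths = self._paths(spec, t, 1500)
        k3 = empirical_cumulant(paths, order=3)
        assert abs(k3.value - rate * a0**3 * dt) < 3.0 * k3.se

    def test_second_cumulant_of_two_point_marks(self):
        dt, a0, rate = 1.0, 0.7, 0.05
        spec = PoissonBathSpec(rate=rate, marks=MarkDistribution("two_point", a0), filter_kappa=0.01)
        t = np.arange(0.0, 401.0) * dt
        paths = self._paths(spec, t, 1200)
        k2 = empirical_cumulant(paths, order=2)
        assert abs(k2.value - rate * a0**2 * dt) < 3.0 * k2.se

    def test_too_few_paths_rejected(self, exp_kernel):
        from nmsse.noise import NoisePath

        t = exp_kernel.tau_grid
        paths = [NoisePath(t, np.zeros_like(t, dtype=complex))] * 10
        with pytest.raises(ValueError, match="at least"):
            empirical_cumulant(paths, order=2)

    def test_filtered_kurtosis_scales_inversely_with_lambda(self):
        """Excess kurtosis of the variance-matched filtered process is
        proportional to 1/Lambda: log-log regression slope ~ -1."""
        from nmsse import variance_match

        kappa = 0.02
        target_var = 1.0
        t = np.arange(0.0, 401.0) * 2.0
        kurts = []
        lams = [0.1, 1.0, 10.0]
        for i, lam in enumerate(lams):
            rate = lam * kappa
            spec = variance_match(
                target_var,
                PoissonBathSpec(rate=rate, marks=MarkDistribution("two_point"), filter_kappa=kappa),
            )
            filt = spec.noise_filter()
            vals = []
            for s in range(600):
                ev = sample_events(spec, t[-1], seed=5_000 * (i + 1) + s)
                z = filter_and_compensate(ev, filt, t).z.real
                vals.append(z[t > 5.0 / kappa])
            x = np.concatenate(vals)
            m2 = x.var()
            kurts.append((((x - x.mean()) ** 4).mean() - 3 * m2**2) / m2**2)
        slope = np.polyfit(np.log(lams), np.log(kurts), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.2)


@pytest.fixture(scope="module")
def vib_model():
    return ModelSpec(
        dimer=DimerSpec(0.1487, 0.001),
        vibronic=VibronicSpec(omega=0.1487, coupling=0.0, fock_cutoff=40),
    )


class TestKicks:

    def test_zero_mark_is_identity(self, vib_model):
        u = kick_unitary(0.0, vib_model)
        assert np.allclose(u, np.eye(vib_model.dim))

    def test_unitarity(self, vib_model):
        u = kick_unitary(0.9, vib_model)
        assert np.abs(u @ u.conj().T - np.eye(vib_model.dim)).max() < 1e-10

    def test_displacement_raises_occupation_by_mark_squared(self, vib_model):
        """U(a) on |D, 0> acts as a displacement of the mode: <n> = a^2
        (displacement-operator algebra vs the matrix exponential)."""
        from scipy.linalg import expm

        from nmsse.model import SIGMA_Z, destroy_operator, donor_vacuum_state

        a = 0.73
        ko = KickOperator(vib_model)
        psi = ko.apply(donor_vacuum_state(vib_model), a)
        nf = vib_model.nfock
        b = destroy_operator(nf)
        n_op = np.kron(np.eye(2), b.conj().T @ b)
        occupation = (psi.conj() @ n_op @ psi).real
        assert occupation == pytest.approx(a**2, abs=1e-6)
        # cross-check the whole unitary against a dense matrix exponential
        gen = np.kron(SIGMA_Z, b + b.conj().T)
        assert np.abs(ko.unitary(a) - expm(-1j * a * gen)).max() < 1e-9

    def test_kick_scale_multiplier(self, vib_model):
        u1 = kick_unitary(0.5, vib_model, kick_scale=2.0)
        u2 = kick_unitary(1.0, vib_model)
        assert np.allclose(u1, u2)

    def test_requires_vibronic_mode(self):
        bare = ModelSpec(dimer=DimerSpec(0.1, 0.1))
        with pytest.raises(ValueError):
            KickOperator(bare)


def test_spawned_seeds_are_stable_and_distinct():
    a = spawn_seeds(123, 8)
    b = spawn_seeds(123, 8)
    c = spawn_seeds(124, 8)
    assert a == b
    assert len(set(a)) == 8
    assert a != c
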