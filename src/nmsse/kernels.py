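"""Bath correlation kernels and derived memory quantities.

Two environment classes drive the stochastic dynamics:

* a *harmonic (Gaussian)* bath specified by a structured spectral density
  J(w) of narrow bands, whose finite-temperature two-time correlation
  function alpha_G(tau) is obtained by frequency quadrature;
* an *anharmonic (compound-Poisson / shot-noise)* bath represented at the
  second-cumulant level by the effective colored kernel
  alpha_P(tau) = A0 exp(-kappa|tau|) cos(w_P tau), realized at the
  trajectory level by filtering discrete events through a causal response
  function phi.

From either kernel the perturbative time-local memory coefficients

    g0(t) = int_0^t alpha(t - s) ds,
    g1(t) = int_0^t alpha(t - s) (t - s) ds,
    g2(t) = int_0^t ds (t - s) alpha(t - s) int_0^s du alpha(s - u)

are computed by cumulative quadrature on the propagation grid.  Variance
matching calibrates the shot-noise bath so that its second cumulant equals
the Gaussian bath's at tau = 0, leaving the event rate free so the
event-per-memory parameter Lambda = lambda_p * tau_c can be scanned at
fixed noise variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import integrate

from .model import ModelSpec, effective_frequency

__all__ = [
    "SpectralDensitySpec",
    "ThermalSpec",
    "MarkDistribution",
    "ExponentialFilter",
    "PoissonBathSpec",
    "CorrelationKernel",
    "MemoryCoefficients",
    "RegimeControls",
    "spectral_density",
    "thermal_occupation",
    "gaussian_kernel",
    "poisson_kernel",
    "filtered_kernel_from_phi",
    "second_jump_moment",
    "memory_coefficients",
    "variance_match",
    "regime_controls",
]


@dataclass(frozen=True)
class SpectralDensitySpec:
    """Structured spectral density: sum of narrow bands centred at
    ``mode_freqs`` (eV) with common coupling strength ``gamma`` (eV) and
    linewidth ``linewidth`` = Gamma (eV)."""

    mode_freqs: Sequence[float]
    gamma: float
    linewidth: float

    def __post_init__(self):
        freqs = tuple(float(w) for w in self.mode_freqs)
        object.__setattr__(self, "mode_freqs", freqs)
        if not freqs:
            raise ValueError("mode_freqs must contain at least one frequency")
        if any(w <= 0 for w in freqs):
            raise ValueError("all mode frequencies must be > 0")
        if self.linewidth <= 0:
            raise ValueError("linewidth must be > 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass(frozen=True)
class ThermalSpec:
    """Bath temperature as k_B T in eV; 0 selects the zero-temperature limit."""

    kbt: float

    def __post_init__(self):
        if self.kbt < 0:
            raise ValueError("kbt must be >= 0")


@dataclass(frozen=True)
class MarkDistribution:
    """Amplitude ("mark") distribution p(a) of the shot-noise events.

    Families
    --------
    ``"two_point"``
        Symmetric +/- scale with probability 1/2 each (zero mean, all even
        moments nonzero).  Default.
    ``"fixed"``
        Degenerate at ``scale`` (nonzero mean; compensation applies).
    ``"gaussian"``
        Zero-mean normal with standard deviation ``scale``.
    """

    family: str = "two_point"
    scale: float = 1.0

    _FAMILIES = ("two_point", "fixed", "gaussian")

    def __post_init__(self):
        if self.family not in self._FAMILIES:
            raise ValueError(f"unknown mark family {self.family!r}; choose from {self._FAMILIES}")
        if not math.isfinite(self.scale):
            raise ValueError("mark scale must be finite")

    def moment(self, n: int) -> float:
        """Raw moment E[a^n]."""
        a = self.scale
        if self.family == "fixed":
            return a**n
        if self.family == "two_point":
            return a**n if n % 2 == 0 else 0.0
        # zero-mean gaussian: E[a^n] = sigma^n (n-1)!! for even n
        if n % 2 == 1:
            return 0.0
        k = n // 2
        double_fact = math.prod(range(1, n, 2)) if n > 0 else 1
        return a**n * double_fact if k > 0 else 1.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "fixed":
            return np.full(size, self.scale)
        if self.family == "two_point":
            return self.scale * rng.choice([-1.0, 1.0], size=size)
        return rng.normal(0.0, abs(self.scale), size=size)

    def with_second_moment(self, m2: float) -> "MarkDistribution":
        """Rescale so that E[a^2] = ``m2`` (family preserved)."""
        if m2 < 0:
            raise ValueError("second moment must be >= 0")
        return replace(self, scale=math.sqrt(m2))


@dataclass(frozen=True)
class ExponentialFilter:
    """Causal response phi(u) = scale * exp(-kappa u) cos(omega u), u >= 0.

    The workhorse filter for the shot-noise bath: ``kappa`` is the inverse
    memory time and ``omega`` an optional modulation frequency.
    """

    kappa: float
    omega: float = 0.0
    scale: float = 1.0

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("filter kappa must be > 0")

    def __call__(self, u):
        u = np.asarray(u, dtype=float)
        out = np.where(u >= 0, self.scale * np.exp(-self.kappa * np.clip(u, 0, None)) * np.cos(self.omega * u), 0.0)
        return out if out.ndim else float(out)

    def norm_sq(self) -> float:
        """int_0^inf phi(u)^2 du, in closed form."""
        k, w, c = self.kappa, self.omega, self.scale
        return c**2 * (1.0 / (4 * k) + k / (4 * (k**2 + w**2)))

    def integral(self, t):
        """Cumulative integral int_0^t phi(u) du (t >= 0), in closed form."""
        t = np.asarray(t, dtype=float)
        z = self.kappa - 1j * self.omega
        val = self.scale * ((1.0 - np.exp(-z * t)) / z).real
        return val if val.ndim else float(val)

    def self_correlation(self, tau, weight: float = 1.0):
        """weight * int_0^inf phi(u + |tau|) phi(u) du, in closed form.

        This is the stationary second-cumulant kernel of a shot-noise
        process filtered through phi, with ``weight`` = lambda_p E[a^2].
        """
        tau = np.abs(np.asarray(tau, dtype=float))
        k, w, c = self.kappa, self.omega, self.scale
        damp = np.exp(-k * tau)
        cos_t, sin_t = np.cos(w * tau), np.sin(w * tau)
        val = weight * c**2 * damp * (
            cos_t / (4 * k) + (k * cos_t - w * sin_t) / (4 * (k**2 + w**2))
        )
        return val if val.ndim else float(val)


@dataclass(frozen=True)
class PoissonBathSpec:
    """Shot-noise bath: event rate ``rate`` = lambda_p (per eV^-1 of time),
    mark distribution p(a), filter memory ``filter_kappa`` = kappa (eV),
    modulation ``filter_omega`` = w_P (eV), and kernel amplitude
    ``amplitude`` = A0 = alpha_P(0).

    When ``amplitude`` is None it is derived from the exponential-filter
    identity A0 = lambda_p E[a^2] / (2 kappa).
    """

    rate: float
    marks: MarkDistribution = field(default_factory=MarkDistribution)
    filter_kappa: float = 0.005
    filter_omega: float = 0.0
    amplitude: Optional[float] = None

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.filter_kappa <= 0:
            raise ValueError("filter_kappa must be > 0")
        if self.amplitude is not None and self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    @property
    def tau_c(self) -> float:
        """Bath correlation time kappa^-1 (eV^-1)."""
        return 1.0 / self.filter_kappa

    @property
    def a0(self) -> float:
        """Kernel amplitude alpha_P(0)."""
        if self.amplitude is not None:
            return self.amplitude
        return second_jump_moment(self) / (2.0 * self.filter_kappa)

    def noise_filter(self) -> ExponentialFilter:
        """Filter used to synthesize trajectory noise, scaled so the
        realized stationary variance equals alpha_P(0) exactly."""
        m2 = second_jump_moment(self)
        base = ExponentialFilter(self.filter_kappa, self.filter_omega, 1.0)
        if m2 <= 0:
            return base
        scale = math.sqrt(self.a0 / (m2 * base.norm_sq()))
        return replace(base, scale=scale)


@dataclass(frozen=True)
class CorrelationKernel:
    """Complex two-time bath kernel alpha(tau) sampled on nonnegative lags.

    Stationary kernels extend to negative lags by alpha(-tau) = alpha(tau)*.
    """

    tau_grid: np.ndarray
    values: np.ndarray
    stationary: bool = True

    def __post_init__(self):
        tau = np.asarray(self.tau_grid, dtype=float)
        vals = np.asarray(self.values, dtype=complex)
        if tau.ndim != 1 or vals.shape != tau.shape:
            raise ValueError("tau_grid and values must be matching 1-D arrays")
        if tau[0] != 0.0 or np.any(np.diff(tau) <= 0):
            raise ValueError("tau_grid must be sorted and start at 0")
        scale = max(1.0, float(np.abs(vals).max(initial=0.0)))
        if abs(vals[0].imag) > 1e-9 * scale or vals[0].real < -1e-9 * scale:
            raise ValueError(f"alpha(0) must be real and >= 0, got {vals[0]}")
        object.__setattr__(self, "tau_grid", tau)
        object.__setattr__(self, "values", vals)

    @property
    def at_zero(self) -> float:
        return float(self.values[0].real)

    def at(self, tau) -> np.ndarray:
        """Interpolated kernel values; negative lags use Hermitian symmetry."""
        tau = np.asarray(tau, dtype=float)
        mag = np.abs(tau)
        re = np.interp(mag, self.tau_grid, self.values.real)
        im = np.interp(mag, self.tau_grid, self.values.imag)
        out = re + 1j * np.where(tau >= 0, im, -im)
        return out if out.ndim else complex(out)

    def to_frame(self):
        """Two-sided export as a pandas DataFrame (tau, re, im)."""
        import pandas as pd

        return pd.DataFrame(
            {"tau": self.tau_grid, "re": self.values.real, "im": self.values.imag}
        )


@dataclass(frozen=True)
class MemoryCoefficients:
    """Time-local memory coefficients g0(t), g1(t) (and optionally g2)
    derived from a correlation kernel on the propagation grid."""

    t_grid: np.ndarray
    g0: np.ndarray
    g1: np.ndarray
    g2: Optional[np.ndarray] = None
    kernel: Optional[CorrelationKernel] = None


@dataclass(frozen=True)
class RegimeControls:
    """Dimensionless regime numbers: system frequency Omega, bath
    correlation time tau_c, system time tau_sys = 1/Omega, the
    non-Markovianity measure eta_NM = Omega tau_c and the event-per-memory
    parameter Lambda = lambda_p tau_c."""

    omega_sys: float
    tau_c: float
    tau_sys: float
    eta_nm: float
    lam: float


def spectral_density(omega, spec: SpectralDensitySpec):
    """Structured spectral density J(w) = sum_i g G w_i^2 w / ((w_i^2 - w^2)^2 + G^2 w^2)."""
    w = np.asarray(omega, dtype=float)
    out = np.zeros_like(w)
    g, G = spec.gamma, spec.linewidth
    for wi in spec.mode_freqs:
        out = out + g * G * wi**2 * w / ((wi**2 - w**2) ** 2 + G**2 * w**2)
    return out if out.ndim else float(out)


def thermal_occupation(omega: float, thermal: ThermalSpec) -> float:
    """Bose occupation n_th = 1 / (exp(omega / kbt) - 1).

    Returns 0 at kbt = 0 by convention (zero-temperature limit).
    """
    if omega <= 0:
        raise ValueError("omega must be > 0")
    if thermal.kbt == 0.0:
        return 0.0
    return 1.0 / math.expm1(omega / thermal.kbt)


def _coth_weight(omega: np.ndarray, spec: SpectralDensitySpec, thermal: ThermalSpec) -> np.ndarray:
    """J(w) * coth(w / 2 kbt) on a grid that may include w = 0.

    The w -> 0 limit is finite for kbt > 0: J(w)/w -> sum_i g G / w_i^2 and
    coth -> 2 kbt / w.
    """
    w = np.asarray(omega, dtype=float)
    out = np.empty_like(w)
    pos = w > 0
    jw = spectral_density(w[pos], spec)
    if thermal.kbt > 0:
        out[pos] = jw / np.tanh(w[pos] / (2.0 * thermal.kbt))
        limit = 2.0 * thermal.kbt * sum(
            spec.gamma * spec.linewidth / wi**2 for wi in spec.mode_freqs
        )
        out[~pos] = limit
    else:
        out[pos] = jw
        out[~pos] = 0.0
    return out


def gaussian_kernel(
    tau_grid,
    spec: SpectralDensitySpec,
    thermal: ThermalSpec,
    *,
    form: str = "full_coth",
    cutoff: Optional[float] = None,
    rtol: float = 1e-7,
    n_start: int = 4001,
    max_refine: int = 8,
) -> CorrelationKernel:
    """Finite-temperature Gaussian bath kernel by frequency quadrature.

    ``form="full_coth"`` evaluates
    alpha(tau) = int_0^inf J(w) coth(w/2kbt) [cos(w tau) - i sin(w tau)] dw
    with coth multiplying both quadratures; ``form="standard"`` uses the
    conventional coth(w/2kbt) cos(w tau) - i sin(w tau) weighting.

    The integral runs to ``cutoff`` (default 10x the largest band centre)
    on a uniform Simpson grid that is refined (doubled) until successive
    estimates agree to ``rtol`` in the sup norm; non-convergence raises
    ``RuntimeError`` with diagnostics.
    """
    if form not in ("full_coth", "standard"):
        raise ValueError(f"unknown kernel form {form!r}")
    tau = np.asarray(tau_grid, dtype=float)
    if cutoff is None:
        cutoff = 10.0 * max(spec.mode_freqs)
    if spec.gamma == 0.0:
        return CorrelationKernel(tau, np.zeros_like(tau, dtype=complex))

    prev = None
    n = int(n_start)
    for _ in range(max_refine):
        omega = np.linspace(0.0, cutoff, n)
        coth_w = _coth_weight(omega, spec, thermal)
        plain_j = spectral_density(omega, spec)
        vals = np.empty(tau.shape, dtype=complex)
        chunk = max(1, int(4e6 // n))
        for i0 in range(0, tau.size, chunk):
            tt = tau[i0 : i0 + chunk, None]
            if form == "full_coth":
                integrand = coth_w[None, :] * np.exp(-1j * omega[None, :] * tt)
            else:
                integrand = (
                    coth_w[None, :] * np.cos(omega[None, :] * tt)
                    - 1j * plain_j[None, :] * np.sin(omega[None, :] * tt)
                )
            vals[i0 : i0 + chunk] = integrate.simpson(integrand, x=omega, axis=1)
        if prev is not None:
            scale = max(1.0, float(np.abs(vals).max()))
            if float(np.abs(vals - prev).max()) <= rtol * scale:
                # zero out the numerically tiny imaginary part at tau = 0
                vals[tau == 0.0] = vals[tau == 0.0].real
                return CorrelationKernel(tau, vals)
        prev = vals
        n = 2 * n - 1
    raise RuntimeError(
        f"gaussian_kernel quadrature did not converge to rtol={rtol} "
        f"within {max_refine} refinements (last n={n // 2 + 1}, cutoff={cutoff})"
    )


def poisson_kernel(tau_grid, spec: PoissonBathSpec) -> CorrelationKernel:
    """Effective colored shot-noise kernel alpha_P(tau) = A0 e^{-k|tau|} cos(w_P tau)."""
    tau = np.asarray(tau_grid, dtype=float)
    vals = spec.a0 * np.exp(-spec.filter_kappa * np.abs(tau)) * np.cos(spec.filter_omega * tau)
    return CorrelationKernel(tau, vals.astype(complex))


def filtered_kernel_from_phi(
    tau_grid,
    phi: Callable[[float], complex],
    jump_moment: float,
    *,
    upper: float = np.inf,
) -> CorrelationKernel:
    """Stationary second-cumulant kernel of a filtered shot-noise process,

        alpha_P(tau) = lambda_p E[a^2] int_0^inf phi(u + |tau|) phi(u)* du,

    by adaptive quadrature.  ``jump_moment`` is lambda_p E[a^2].  For the
    exponential filter phi(u) = e^{-k u} this reduces to
    lambda_p E[a^2] e^{-k|tau|} / (2k).  A divergent filter norm raises.
    """
    tau = np.asarray(tau_grid, dtype=float)

    def _corr(lag: float) -> complex:
        re, re_err = integrate.quad(
            lambda u: (phi(u + lag) * np.conj(phi(u))).real, 0.0, upper, limit=200
        )
        im, _ = integrate.quad(
            lambda u: (phi(u + lag) * np.conj(phi(u))).imag, 0.0, upper, limit=200
        )
        if not (math.isfinite(re) and math.isfinite(im)):
            raise ValueError("filter correlation integral diverges")
        return re + 1j * im

    norm = _corr(0.0)
    if abs(norm) > 1e12:
        raise ValueError("filter norm too large; phi is not square-integrable")
    vals = jump_moment * np.array([_corr(abs(t)) for t in tau])
    vals[tau == 0.0] = vals[tau == 0.0].real
    return CorrelationKernel(tau, vals)


def second_jump_moment(spec: PoissonBathSpec) -> float:
    """Second jump moment int a^2 nu(da) = lambda_p E[a^2]."""
    return spec.rate * spec.marks.moment(2)


def memory_coefficients(
    kernel: CorrelationKernel,
    t_grid,
    order: int = 1,
) -> MemoryCoefficients:
    """Cumulative-quadrature memory coefficients on ``t_grid``.

    g0(t) = int_0^t alpha(u) du and g1(t) = int_0^t u alpha(u) du
    (after the substitution u = t - s in the defining integrals);
    ``order`` = 2 additionally evaluates the nested double integral
    g2(t) = int_0^t ds (t-s) alpha(t-s) g0(s) by discrete convolution.
    """
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t[0] != 0.0 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be sorted, 1-D and start at 0")
    if t[-1] > kernel.tau_grid[-1] + 1e-12:
        raise ValueError("kernel lags do not cover the requested time grid")
    alpha = kernel.at(t)
    if t.size >= 3:
        g0 = integrate.cumulative_simpson(alpha, x=t, initial=0.0)
        g1 = (
            integrate.cumulative_simpson(alpha * t, x=t, initial=0.0)
            if order >= 1
            else np.zeros_like(g0)
        )
    else:
        g0 = np.concatenate([[0.0], integrate.cumulative_trapezoid(alpha, t)])
        g1 = (
            np.concatenate([[0.0], integrate.cumulative_trapezoid(alpha * t, t)])
            if order >= 1
            else np.zeros_like(g0)
        )
    g2 = None
    if order == 2:
        if t.size < 8:
            raise ValueError("t_grid too coarse for the order-2 double integral")
        dt = float(t[1] - t[0])
        if np.max(np.abs(np.diff(t) - dt)) > 1e-9 * dt:
            raise ValueError("order-2 coefficients require a uniform grid")
        h = t * alpha  # (t-s) alpha(t-s) sampled on lags
        g2 = np.empty_like(g0)
        g2[0] = 0.0
        for m in range(1, t.size):
            w = np.full(m + 1, dt)
            w[0] *= 0.5
            w[-1] *= 0.5
            g2[m] = np.dot(w, h[m::-1] * g0[: m + 1])
    return MemoryCoefficients(t_grid=t, g0=g0, g1=g1, g2=g2, kernel=kernel)


def variance_match(target: CorrelationKernel | float, spec: PoissonBathSpec) -> PoissonBathSpec:
    """Calibrate a shot-noise bath to a target kernel at the second cumulant.

    Sets A0 = Re alpha(0) of the target and rescales the marks so that
    lambda_p E[a^2] = 2 kappa A0 (the exponential-filter identity), leaving
    the event rate free so Lambda can be scanned at fixed variance.
    Idempotent; preserves Re alpha(0) exactly.
    """
    a0 = target.at_zero if isinstance(target, CorrelationKernel) else float(target)
    if a0 < 0:
        raise ValueError("target variance must be >= 0")
    if spec.rate == 0.0 and a0 > 0:
        raise ValueError("cannot variance-match a zero-rate bath to a nonzero target")
    m2 = 2.0 * spec.filter_kappa * a0 / spec.rate if spec.rate > 0 else 0.0
    return replace(spec, amplitude=a0, marks=spec.marks.with_second_moment(m2))


def regime_controls(model: ModelSpec, gamma_bath: float, rate: float = 0.0) -> RegimeControls:
    """Dimensionless regime numbers from the model and bath width.

    ``gamma_bath`` is the inverse memory time of the bath (the spectral
    linewidth Gamma for the Gaussian bath, or kappa for the shot-noise
    bath); ``rate`` is the event rate lambda_p (0 for a Gaussian bath).
    """
    if gamma_bath <= 0:
        raise ValueError("gamma_bath must be > 0")
    omega = effective_frequency(model.dimer)
    tau_c = 1.0 / gamma_bath
    tau_sys = 1.0 / omega if omega > 0 else math.inf
    return RegimeControls(
        omega_sys=omega,
        tau_c=tau_c,
        tau_sys=tau_sys,
        eta_nm=omega * tau_c,
        lam=rate * tau_c,
    )
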