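"""Per-trajectory driving processes.

Gaussian bath: zero-mean circularly-symmetric complex colored noise with a
prescribed two-time kernel, synthesized from the eigendecomposition of the
Hermitian covariance matrix on the time grid.

Shot-noise bath: marked Poisson events filtered through a causal response
function and compensated to zero mean, plus unitary "kick" operators that
act impulsively on the coupled electronic-vibrational manifold at the event
times.  One event stream drives both the colored noise and the kicks of a
trajectory, so each trajectory has a single source of randomness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import linalg, stats

from .kernels import CorrelationKernel, ExponentialFilter, PoissonBathSpec
from .model import SIGMA_Z, ModelSpec, destroy_operator

__all__ = [
    "EventStream",
    "NoisePath",
    "GaussianPathFactory",
    "sample_gaussian_path",
    "sample_events",
    "filter_and_compensate",
    "compensated_jump_path",
    "CumulantEstimate",
    "empirical_cumulant",
    "KickOperator",
    "kick_unitary",
    "spawn_seeds",
    "dump_paths_hdf5",
]


@dataclass(frozen=True)
class EventStream:
    """Sorted Poisson event times with i.i.d. marks drawn from p(a).

    ``phases`` optionally carries i.i.d. uniform phases that circularize
    the filtered noise channel (E[zz] = 0); kicks always use the real
    marks.
    """

    times: np.ndarray
    marks: np.ndarray
    rate: float
    phases: Optional[np.ndarray] = None

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        marks = np.asarray(self.marks, dtype=float)
        if times.shape != marks.shape or times.ndim != 1:
            raise ValueError("times and marks must be matching 1-D arrays")
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("event times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "marks", marks)
        if self.phases is not None:
            phases = np.asarray(self.phases, dtype=float)
            if phases.shape != times.shape:
                raise ValueError("phases must match times")
            object.__setattr__(self, "phases", phases)

    def __len__(self) -> int:
        return self.times.size

    def clip(self, t_min: float, t_max: float) -> "EventStream":
        """Sub-stream of events with t_min < t <= t_max."""
        keep = (self.times > t_min) & (self.times <= t_max)
        return EventStream(
            times=self.times[keep],
            marks=self.marks[keep],
            rate=self.rate,
            phases=self.phases[keep] if self.phases is not None else None,
        )


@dataclass(frozen=True)
class NoisePath:
    """One realization of the driving process z_t on the grid, with the
    underlying event stream when the path is shot-noise driven."""

    t_grid: np.ndarray
    z: np.ndarray
    events: Optional[EventStream] = None
    seed: Optional[int] = None

    def __post_init__(self):
        t = np.asarray(self.t_grid, dtype=float)
        z = np.asarray(self.z, dtype=complex)
        if z.shape != t.shape:
            raise ValueError("z and t_grid must have matching shapes")
        if self.events is not None and self.events.times.size:
            if self.events.times[0] < 0 or self.events.times[-1] > t[-1]:
                raise ValueError("event times must lie within [0, t_max]")
        object.__setattr__(self, "t_grid", t)
        object.__setattr__(self, "z", z)


def spawn_seeds(master_seed: int, n: int, *, stream: int = 0) -> list[int]:
    """Derive ``n`` per-trajectory integer seeds from a master seed with a
    counter-based SeedSequence scheme (reproducible under chunked or
    parallel execution)."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(stream,))
    return [int(s.generate_state(1)[0]) for s in ss.spawn(n)]


class GaussianPathFactory:
    """Sampler of colored complex Gaussian paths with E[z_t z_s*] = alpha(t-s).

    Builds the Hermitian covariance matrix on the grid once, takes its
    eigendecomposition, clips eigenvalues in [-clip_tol * lam_max, 0) to
    zero and raises for indefiniteness beyond that tolerance.  Paths are
    circularly symmetric: E[z_t z_s] = 0.
    """

    def __init__(self, kernel: CorrelationKernel, t_grid, *, clip_tol: float = 1e-10):
        t = np.asarray(t_grid, dtype=float)
        lags = t - t[0]
        alpha = kernel.at(lags)
        cov = linalg.toeplitz(alpha, alpha.conj())
        w, u = linalg.eigh(cov)
        wmax = float(max(w.max(initial=0.0), 0.0))
        if np.any(w < -clip_tol * max(wmax, 1e-300)):
            raise ValueError(
                f"kernel covariance is indefinite beyond tolerance: "
                f"min eigenvalue {w.min():.3e}, max {wmax:.3e}"
            )
        w = np.clip(w, 0.0, None)
        self.t_grid = t
        self._b = u * np.sqrt(w)[None, :]

    def sample(self, n: int, seed) -> np.ndarray:
        """Draw ``n`` paths; returns an (n, len(t_grid)) complex array."""
        rng = np.random.default_rng(seed)
        m = self.t_grid.size
        white = (rng.standard_normal((m, n)) + 1j * rng.standard_normal((m, n))) / np.sqrt(2.0)
        return (self._b @ white).T


def sample_gaussian_path(kernel: CorrelationKernel, t_grid, seed) -> NoisePath:
    """One colored complex Gaussian realization; reproducible from ``seed``."""
    factory = GaussianPathFactory(kernel, t_grid)
    z = factory.sample(1, seed)[0]
    return NoisePath(t_grid=np.asarray(t_grid, dtype=float), z=z, seed=_as_seed_int(seed))


def _as_seed_int(seed) -> Optional[int]:
    return int(seed) if np.isscalar(seed) else None


def sample_events(
    spec: PoissonBathSpec,
    t_max: float,
    seed,
    *,
    t_start: float = 0.0,
    with_phases: bool = False,
) -> EventStream:
    """Homogeneous Poisson arrivals on [t_start, t_max] at rate lambda_p
    with i.i.d. marks; exponential inter-arrival times, reproducible from
    seed.  ``t_start < 0`` provides a stationary burn-in for the filtered
    process; ``with_phases`` attaches uniform phases for the circular
    noise channel."""
    rng = np.random.default_rng(seed)
    times = []
    if spec.rate > 0:
        t = t_start + rng.exponential(1.0 / spec.rate)
        while t < t_max:
            times.append(t)
            t += rng.exponential(1.0 / spec.rate)
    times = np.asarray(times, dtype=float)
    marks = spec.marks.sample(rng, times.size)
    phases = rng.uniform(0.0, 2.0 * np.pi, times.size) if with_phases else None
    return EventStream(times=times, marks=marks, rate=spec.rate, phases=phases)


def filter_and_compensate(
    events: EventStream,
    filt: ExponentialFilter,
    t_grid,
    *,
    mark_mean: float = 0.0,
) -> NoisePath:
    """Filtered, compensated shot-noise path on the grid:

        z(t) = sum_k phi(t - t_k) a_k e^{i theta_k}
               - lambda_p E[a e^{i theta}] int_0^t phi(u) du.

    The compensation term vanishes for zero-mean marks and always for
    phased (circular) streams.  Without phases the path is real; with
    phases it is a circularly-symmetric complex process whose covariance
    E[z z*] is unchanged while E[z z] = 0.  Event times before the grid
    origin contribute their decayed response (stationary burn-in).
    """
    t = np.asarray(t_grid, dtype=float)
    z = np.zeros(t.shape, dtype=complex)
    if len(events):
        amps = events.marks.astype(complex)
        if events.phases is not None:
            amps = amps * np.exp(1j * events.phases)
        lag = t[:, None] - events.times[None, :]
        z = (filt(lag) * amps[None, :]).sum(axis=1)
    if mark_mean != 0.0 and events.rate > 0.0 and events.phases is None:
        z = z - events.rate * mark_mean * filt.integral(np.clip(t, 0.0, None))
    in_window = events.clip(0.0, t[-1]) if len(events) else events
    return NoisePath(t_grid=t, z=z, events=in_window)


def compensated_jump_path(events: EventStream, t_grid, *, mark_mean: float = 0.0) -> NoisePath:
    """Unfiltered compensated compound-Poisson path
    X(t) = sum_{t_k <= t} a_k - lambda_p E[a] t, whose per-step increment
    cumulants satisfy kappa_n[dX] = lambda_p E[a^n] dt for n >= 2."""
    t = np.asarray(t_grid, dtype=float)
    x = np.zeros_like(t)
    if len(events):
        idx = np.searchsorted(events.times, t, side="right")
        csum = np.concatenate([[0.0], np.cumsum(events.marks)])
        x = csum[idx]
    x = x - events.rate * mark_mean * t
    return NoisePath(t_grid=t, z=x.astype(complex), events=events)


@dataclass(frozen=True)
class CumulantEstimate:
    order: int
    value: float
    se: float


def empirical_cumulant(
    paths: Sequence[NoisePath],
    order: int,
    *,
    min_paths: int = 1000,
) -> CumulantEstimate:
    """Unbiased k-statistic of the per-step increments of an ensemble.

    The cumulant of order 2, 3 or 4 is estimated per path from the real
    part of the increments (the shot-noise process is real; colored
    Gaussian paths have circularly symmetric components) and averaged over
    paths, with the standard error across paths attached.
    """
    if order not in (2, 3, 4):
        raise ValueError("order must be 2, 3 or 4")
    if len(paths) < min_paths:
        raise ValueError(f"need at least {min_paths} paths, got {len(paths)}")
    per_path = np.array(
        [stats.kstat(np.diff(p.z.real), n=order) for p in paths], dtype=float
    )
    return CumulantEstimate(
        order=order,
        value=float(per_path.mean()),
        se=float(per_path.std(ddof=1) / np.sqrt(len(paths))),
    )


class KickOperator:
    """Unitary event kick U(a) = exp(-i a * kick_scale * K) with generator
    K = sigma_z (x) (b + b^dagger) by default.

    The generator is diagonalized once so that per-event application costs
    two small matrix-vector products.
    """

    def __init__(
        self,
        model: ModelSpec,
        *,
        generator: Optional[np.ndarray] = None,
        kick_scale: float = 1.0,
    ):
        if generator is None:
            if model.vibronic is None:
                raise ValueError("default kick generator requires a vibronic mode")
            b = destroy_operator(model.nfock)
            generator = np.kron(SIGMA_Z, b + b.conj().T)
        k = np.asarray(generator, dtype=complex)
        if k.shape != (model.dim, model.dim):
            raise ValueError(f"generator must be {model.dim}x{model.dim}")
        if not np.allclose(k, k.conj().T, atol=1e-12):
            raise ValueError("kick generator must be Hermitian")
        self.kick_scale = float(kick_scale)
        self._eigvals, self._eigvecs = linalg.eigh(k)

    def unitary(self, mark: float) -> np.ndarray:
        """Dense unitary for a single kick of amplitude ``mark``."""
        phase = np.exp(-1j * mark * self.kick_scale * self._eigvals)
        u = (self._eigvecs * phase[None, :]) @ self._eigvecs.conj().T
        defect = float(np.abs(u @ u.conj().T - np.eye(u.shape[0])).max())
        if defect > 1e-8:
            warnings.warn(f"kick unitary defect {defect:.2e} exceeds 1e-8 (truncation)")
        return u

    def apply(self, psi: np.ndarray, mark: float) -> np.ndarray:
        """Apply U(mark) to a state (or batch of row states)."""
        phase = np.exp(-1j * mark * self.kick_scale * self._eigvals)
        coeff = psi @ self._eigvecs.conj()
        return (coeff * phase) @ self._eigvecs.T


def kick_unitary(
    mark: float,
    model: ModelSpec,
    *,
    generator: Optional[np.ndarray] = None,
    kick_scale: float = 1.0,
) -> np.ndarray:
    """Convenience wrapper returning the dense kick unitary U(mark)."""
    return KickOperator(model, generator=generator, kick_scale=kick_scale).unitary(mark)


def dump_paths_hdf5(path, noise_paths: Sequence[NoisePath]) -> None:
    """Debug dump of paths and their events to an HDF5 container with the
    schema /paths/{i}/z, /paths/{i}/events."""
    import h5py

    with h5py.File(path, "w") as fh:
        grp = fh.create_group("paths")
        for i, p in enumerate(noise_paths):
            g = grp.create_group(str(i))
            g.create_dataset("t", data=p.t_grid)
            g.create_dataset("z", data=p.z)
            if p.events is not None:
                ev = np.column_stack([p.events.times, p.events.marks])
                g.create_dataset("events", data=ev)
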