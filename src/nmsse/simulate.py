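"""High-level drivers: one ensemble run, and DeltaP regime maps.

`run_ensemble` wires the pieces together for a given bath description:
build the time grid, evaluate the bath kernel and memory coefficients on
it, synthesize per-trajectory noise (colored Gaussian, or filtered and
compensated shot noise sharing its event stream with the unitary kicks),
propagate the nonlinear NMSSE in vectorized chunks, and stream the states
into the ensemble accumulator.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Optional, Sequence, Union

import numpy as np

from .integrator import IntegratorConfig, propagate_batch
from .kernels import (
    CorrelationKernel,
    MemoryCoefficients,
    PoissonBathSpec,
    SpectralDensitySpec,
    ThermalSpec,
    gaussian_kernel,
    memory_coefficients,
    poisson_kernel,
    variance_match,
)
from .model import ModelSpec, effective_frequency
from .noise import (
    EventStream,
    GaussianPathFactory,
    KickOperator,
    filter_and_compensate,
    sample_events,
    spawn_seeds,
)
from .observables import EnsembleAccumulator, EnsembleResult, ScanResult, delta_p

__all__ = ["default_time_grid", "run_ensemble", "scan_map"]

BathSpec = Union[SpectralDensitySpec, PoissonBathSpec, CorrelationKernel, None]


def default_time_grid(model: ModelSpec, dt: float, *, n_periods: float = 10.0) -> np.ndarray:
    """Uniform grid covering ``n_periods`` Rabi periods of the dimer."""
    omega = effective_frequency(model.dimer)
    if omega <= 0:
        raise ValueError("cannot size the window for a zero-frequency dimer")
    t_max = n_periods * 2.0 * math.pi / omega
    n_steps = int(math.ceil(t_max / dt))
    return np.arange(n_steps + 1) * dt


def _zero_kernel(t_grid: np.ndarray) -> CorrelationKernel:
    return CorrelationKernel(t_grid, np.zeros_like(t_grid, dtype=complex))


def build_bath_kernel(
    bath: BathSpec,
    t_grid: np.ndarray,
    thermal: Optional[ThermalSpec],
    *,
    kernel_form: str = "full_coth",
    cutoff: Optional[float] = None,
) -> CorrelationKernel:
    """Bath kernel sampled on the propagation grid's lags."""
    if bath is None:
        return _zero_kernel(t_grid)
    if isinstance(bath, SpectralDensitySpec):
        if thermal is None:
            raise ValueError("a Gaussian bath needs a ThermalSpec")
        return gaussian_kernel(t_grid, bath, thermal, form=kernel_form, cutoff=cutoff)
    if isinstance(bath, PoissonBathSpec):
        return poisson_kernel(t_grid, bath)
    if isinstance(bath, CorrelationKernel):
        return bath
    raise TypeError(f"unsupported bath spec {type(bath).__name__}")


def run_ensemble(
    model: ModelSpec,
    bath: BathSpec,
    config: IntegratorConfig,
    n_traj: int,
    master_seed: int,
    *,
    thermal: Optional[ThermalSpec] = None,
    t_grid: Optional[np.ndarray] = None,
    n_periods: float = 10.0,
    kernel: Optional[CorrelationKernel] = None,
    kernel_form: str = "full_coth",
    cutoff: Optional[float] = None,
    init_state: Optional[np.ndarray] = None,
    with_kicks: bool = True,
    kick_scale: Optional[float] = None,
    circular_noise: bool = True,
    burn_in_factor: float = 8.0,
    chunk_size: int = 500,
) -> EnsembleResult:
    """Propagate an ensemble and return the averaged reduced dynamics.

    ``bath`` selects the noise statistics: a ``SpectralDensitySpec`` (with
    ``thermal``) drives colored complex Gaussian noise, a bare
    ``CorrelationKernel`` drives colored Gaussian noise with exactly that
    kernel (the variance-matched reference for shot-noise comparisons), a
    ``PoissonBathSpec`` drives filtered compensated shot noise plus
    unitary kicks, and ``None`` gives deterministic closed-system
    evolution.  An explicit ``kernel`` overrides the kernel used for the
    memory coefficients and noise shift.

    Shot-noise conventions: events are sampled from ``-burn_in_factor /
    kappa`` onward so the filtered process is stationary at t = 0; marks
    carry uniform random phases in the noise channel when
    ``circular_noise`` (matching the circular Gaussian convention at the
    second cumulant); kick angles default to ``gamma_nj * mark``
    (``kick_scale=None``), scaling the event channel with the same
    coupling amplitude as the noise channel.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    if t_grid is None:
        t_grid = default_time_grid(model, config.dt, n_periods=n_periods)
    t_grid = np.asarray(t_grid, dtype=float)
    if kernel is None:
        kernel = build_bath_kernel(bath, t_grid, thermal, kernel_form=kernel_form, cutoff=cutoff)
    coeffs = memory_coefficients(kernel, t_grid, order=1)

    is_poisson = isinstance(bath, PoissonBathSpec)
    kick = None
    if is_poisson and with_kicks and model.vibronic is not None:
        scale = model.gamma_nj if kick_scale is None else kick_scale
        if scale > 0.0:
            kick = KickOperator(model, kick_scale=scale)

    acc = EnsembleAccumulator(model, t_grid)
    seeds = spawn_seeds(master_seed, n_traj)
    gauss_factory = None
    if not is_poisson and bath is not None:
        gauss_factory = GaussianPathFactory(kernel, t_grid)

    filt = bath.noise_filter() if is_poisson else None
    mark_mean = bath.marks.moment(1) if is_poisson else 0.0

    for start in range(0, n_traj, chunk_size):
        chunk_seeds = seeds[start : start + chunk_size]
        b = len(chunk_seeds)
        if bath is None:
            z = np.zeros((b, t_grid.size), dtype=complex)
            events: Optional[Sequence[EventStream]] = None
        elif is_poisson:
            t_burn = burn_in_factor / bath.filter_kappa
            streams = [
                sample_events(
                    bath, t_grid[-1], s, t_start=-t_burn, with_phases=circular_noise
                )
                for s in chunk_seeds
            ]
            paths = [
                filter_and_compensate(ev, filt, t_grid, mark_mean=mark_mean)
                for ev in streams
            ]
            z = np.stack([p.z for p in paths])
            events = [p.events for p in paths] if kick is not None else None
        else:
            z = gauss_factory.sample(b, np.random.SeedSequence(chunk_seeds))
            events = None
        propagate_batch(
            model,
            coeffs,
            z,
            config,
            init_state=init_state,
            events=events,
            kick=kick,
            observer=acc,
            store_states=False,
        )
    return acc.finalize(master_seed=master_seed)


def _regime_label(lam: Optional[float]) -> str:
    if lam is None:
        return "gaussian"
    if lam >= 3.0:
        return "weak"
    if lam > 1.0 / 3.0:
        return "intermediate"
    return "strong"


def scan_map(
    model: ModelSpec,
    config: IntegratorConfig,
    n_traj: int,
    master_seed: int,
    *,
    axes: dict,
    bath_kinds: Sequence[str] = ("gaussian",),
    gaussian_bath: Optional[SpectralDensitySpec] = None,
    poisson_bath: Optional[PoissonBathSpec] = None,
    thermal: Optional[ThermalSpec] = None,
    t_grid: Optional[np.ndarray] = None,
    n_periods: float = 3.0,
    kernel_form: str = "full_coth",
    with_kicks: bool = True,
    kick_scale: Optional[float] = None,
    chunk_size: int = 500,
) -> ScanResult:
    """DeltaP map over parameter axes for one or both bath kinds.

    ``axes`` maps axis names to value lists; supported names are
    ``"delta"`` (electronic coupling, eV), ``"coupling"`` (dimensionless
    vibronic coupling) and ``"lam"`` (event-per-memory parameter Lambda,
    shot-noise runs only).  Each cell runs a matched pair of ensembles
    (vibronic coupling on / set to zero with the mode retained) and
    records DeltaP with its MC standard error; cell failures are recorded
    and the scan continues.

    Shot-noise cells are variance-matched to the Gaussian bath's kernel at
    tau = 0 when a ``gaussian_bath`` is supplied.
    """
    import pandas as pd

    unknown = set(axes) - {"delta", "coupling", "lam"}
    if unknown:
        raise ValueError(f"unsupported scan axes: {sorted(unknown)}")
    deltas = list(axes.get("delta", [model.dimer.delta]))
    couplings = list(
        axes.get("coupling", [model.vibronic.coupling if model.vibronic else 0.0])
    )
    lams = list(axes.get("lam", [None]))

    alpha0 = None
    if gaussian_bath is not None and thermal is not None:
        probe = gaussian_kernel(np.array([0.0]), gaussian_bath, thermal, form=kernel_form)
        alpha0 = probe.at_zero

    ss = np.random.SeedSequence(master_seed)
    rows = []
    for kind in bath_kinds:
        if kind not in ("gaussian", "poisson"):
            raise ValueError(f"unknown bath kind {kind!r}")
        for dlt in deltas:
            for g_vib in couplings:
                for lam in lams if kind == "poisson" else [None]:
                    cell_seed = int(ss.spawn(1)[0].generate_state(1)[0])
                    row = {
                        "delta": dlt,
                        "coupling": g_vib,
                        "lam": lam,
                        "bath": kind,
                        "regime": _regime_label(lam if kind == "poisson" else None),
                        "seed": cell_seed,
                    }
                    try:
                        m_with = replace(
                            model,
                            dimer=replace(model.dimer, delta=dlt),
                            vibronic=replace(model.vibronic, coupling=g_vib)
                            if model.vibronic
                            else None,
                        )
                        m_without = replace(
                            m_with,
                            vibronic=replace(m_with.vibronic, coupling=0.0)
                            if m_with.vibronic
                            else None,
                        )
                        if kind == "gaussian":
                            bath: BathSpec = gaussian_bath
                        else:
                            if poisson_bath is None:
                                raise ValueError("poisson scan requires poisson_bath")
                            bath = poisson_bath
                            if lam is not None:
                                bath = replace(bath, rate=lam * bath.filter_kappa)
                            if alpha0 is not None:
                                bath = variance_match(alpha0, bath)
                        common = dict(
                            thermal=thermal,
                            t_grid=t_grid,
                            n_periods=n_periods,
                            kernel_form=kernel_form,
                            with_kicks=with_kicks,
                            kick_scale=kick_scale,
                            chunk_size=chunk_size,
                        )
                        res_with = run_ensemble(
                            m_with, bath, config, n_traj, cell_seed, **common
                        )
                        res_without = run_ensemble(
                            m_without, bath, config, n_traj, cell_seed + 1, **common
                        )
                        dp = delta_p(res_with, res_without)
                        i_w = int(np.argmax(res_with.p_acceptor))
                        i_o = int(np.argmax(res_without.p_acceptor))
                        se = float(
                            np.hypot(
                                res_with.se_p_acceptor[i_w], res_without.se_p_acceptor[i_o]
                            )
                        )
                        row.update(
                            delta_p=dp,
                            se=se,
                            max_p_with=float(res_with.p_acceptor.max()),
                            max_p_without=float(res_without.p_acceptor.max()),
                            error="",
                        )
                    except Exception as exc:  # record and continue
                        row.update(
                            delta_p=np.nan,
                            se=np.nan,
                            max_p_with=np.nan,
                            max_p_without=np.nan,
                            error=f"{type(exc).__name__}: {exc}",
                        )
                    rows.append(row)
    table = pd.DataFrame(rows)
    meta = {
        "n_traj": n_traj,
        "master_seed": master_seed,
        "bath_kinds": list(bath_kinds),
        "axes": {k: list(v) for k, v in axes.items()},
        "variance_matched": alpha0 is not None,
        "alpha0": alpha0,
    }
    return ScanResult(table=table, axes=dict(axes), metadata=meta)
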