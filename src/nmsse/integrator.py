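"""Propagation of single normalized trajectories of the perturbative
time-local nonlinear NMSSE.

For the dephasing-type coupling L = gamma_nj * sigma_z the equation of
motion implemented here is (operators act on the electronic factor)

    d/dt psi = -i H_S psi
               + gamma_nj (sigma_z - <sigma_z>) psi * conj(ztilde_t)
               - g0(t) gamma_nj^2 [ (sigma_z - <sigma_z>) sigma_z
                                    - <(sigma_z - <sigma_z>) sigma_z> ] psi
               + i g1(t) gamma_nj^2 Delta [ (sigma_z - <sigma_z>) sigma_y
                                    - f <(sigma_z - <sigma_z>) sigma_y> ] psi

where ztilde is the Girsanov-shifted noise

    ztilde_t = z_t + int_0^t alpha(t - s) <L^dagger>_s ds

with the trajectory's own causal expectation history, and f (default 2) is
a configurable bracket factor.  The memory coefficients g0, g1 come from
cumulative quadrature of the bath kernel on the same grid.

The default scheme ("splitting") is a Strang split that applies the
Hamiltonian flow exactly through precomputed exp(-i H dt/2) factors and a
stochastic Heun (predictor-corrector) update to the remaining bath terms;
the exact unitary factors remove the stiffness of the upper Fock-ladder
phases, so the step is limited by the bath terms alone.  Plain Heun and an
order-4 Runge-Kutta variant on the unsplit equation are also available.
All schemes treat the colored noise as smooth within a step — valid when
the bath correlation time far exceeds the step, the operating regime here.
States are renormalized after every step, and for shot-noise baths the
unitary event kicks are applied between steps (Trotter-style splitting)
from the same event stream that generated the driving noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .kernels import CorrelationKernel, MemoryCoefficients
from .model import (
    SIGMA_Y,
    SIGMA_Z,
    ModelSpec,
    build_system_hamiltonian,
    donor_vacuum_state,
    effective_frequency,
    electronic_operator,
)
from .noise import KickOperator, NoisePath

__all__ = [
    "IntegratorConfig",
    "TrajectoryResult",
    "shifted_noise",
    "drift",
    "propagate_trajectory",
    "propagate_batch",
]

_NORM_FLOOR = 1e-12


@dataclass(frozen=True)
class IntegratorConfig:
    """Stepping parameters.

    ``dt`` is the step in eV^-1; ``scheme`` is "splitting" (Strang split
    with exact Hamiltonian half-steps, default), "heun" or "rk4";
    states are renormalized every ``renormalize_every`` steps.  By default
    dt * Omega <= 0.05 is enforced against the model's electronic
    frequency (set ``enforce_step_limit=False`` to override).
    ``g1_bracket_factor`` is the factor multiplying the expectation bracket
    of the g1 term (default 2).
    """

    dt: float
    scheme: str = "splitting"
    renormalize_every: int = 1
    include_g2: bool = False
    g1_bracket_factor: float = 2.0
    max_dt_omega: float = 0.05
    enforce_step_limit: bool = True

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.scheme not in ("splitting", "heun", "rk4"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.renormalize_every < 1:
            raise ValueError("renormalize_every must be >= 1")

    def validate_for(self, model: ModelSpec) -> None:
        omega = effective_frequency(model.dimer)
        if self.enforce_step_limit and self.dt * omega > self.max_dt_omega + 1e-12:
            raise ValueError(
                f"dt * Omega = {self.dt * omega:.3g} exceeds {self.max_dt_omega}; "
                "reduce dt or relax enforce_step_limit"
            )


@dataclass(frozen=True)
class TrajectoryResult:
    """Normalized state series of one trajectory, with the
    pre-normalization norm recorded at each step."""

    t_grid: np.ndarray
    psi: np.ndarray  # (n_times, dim), unit norm rows
    norms: np.ndarray
    seed: Optional[int] = None


def shifted_noise(
    path: NoisePath,
    kernel: Optional[CorrelationKernel],
    expectations: np.ndarray,
) -> np.ndarray:
    """Girsanov-shifted noise on the full grid,
    ztilde_t = z_t + int_0^t alpha(t - s) <L^dagger>_s ds, evaluated by the
    same cumulative trapezoid rule the memory coefficients use.

    ``expectations`` is the causal <L^dagger> history sampled on the grid.
    """
    t = path.t_grid
    z = np.asarray(path.z, dtype=complex)
    exp_hist = np.asarray(expectations, dtype=complex)
    if exp_hist.shape != t.shape:
        raise ValueError("expectation history must match the time grid")
    if kernel is None:
        return z.copy()
    alpha = kernel.at(t - t[0])
    dt = np.diff(t)
    out = z.copy()
    for n in range(1, t.size):
        w = np.empty(n + 1)
        w[1:] = dt[:n]
        w[0] = 0.0
        w[:-1] += dt[:n]
        w *= 0.5
        out[n] += np.dot(w, alpha[n::-1] * exp_hist[: n + 1])
    return out


class _DriftOperators:
    """Precomputed lifted operators for the Eq.-of-motion evaluation."""

    def __init__(self, model: ModelSpec):
        self.model = model
        self.h = build_system_hamiltonian(model)
        self.sz = electronic_operator(SIGMA_Z, model)
        self.sy = electronic_operator(SIGMA_Y, model)
        self.szsz = self.sz @ self.sz
        self.szsy = self.sz @ self.sy
        self.gamma = model.gamma_nj
        self.delta = model.dimer.delta
        # transposed copies: states are row vectors, psi @ op.T == (op psi)^T
        self.hT = self.h.T.copy()
        self.szT = self.sz.T.copy()
        self.syT = self.sy.T.copy()
        self.szszT = self.szsz.T.copy()
        self.szsyT = self.szsy.T.copy()


def _expect(psi: np.ndarray, op_psi: np.ndarray, norm2: np.ndarray) -> np.ndarray:
    return np.einsum("bi,bi->b", psi.conj(), op_psi) / norm2


def _drift_batch(
    ops: _DriftOperators,
    psi: np.ndarray,
    zeta: np.ndarray,
    g0: complex,
    g1: complex,
    bracket_factor: float,
    include_h: bool = True,
) -> np.ndarray:
    """Drift for a (B, dim) batch of (not necessarily normalized) states.

    Expectations are norm-corrected internally; ``zeta`` is the conjugated
    shifted noise per trajectory.  ``include_h=False`` evaluates only the
    bath terms (used by the split-step scheme, which applies the
    Hamiltonian flow exactly).
    """
    norm2 = np.einsum("bi,bi->b", psi.conj(), psi).real
    out = -1j * (psi @ ops.hT) if include_h else np.zeros_like(psi)
    if ops.gamma == 0.0:
        return out
    sz_psi = psi @ ops.szT
    ez = _expect(psi, sz_psi, norm2).real
    out += ops.gamma * zeta[:, None] * (sz_psi - ez[:, None] * psi)

    g2amp = ops.gamma**2
    szsz_psi = psi @ ops.szszT
    ezz = _expect(psi, szsz_psi, norm2).real
    out -= g0 * g2amp * (szsz_psi - ez[:, None] * sz_psi - (ezz - ez**2)[:, None] * psi)

    if ops.delta != 0.0 and g1 != 0.0:
        sy_psi = psi @ ops.syT
        szsy_psi = psi @ ops.szsyT
        ey = _expect(psi, sy_psi, norm2).real
        ezy = _expect(psi, szsy_psi, norm2)
        out += (
            1j
            * g1
            * g2amp
            * ops.delta
            * (szsy_psi - ez[:, None] * sy_psi - bracket_factor * (ezy - ez * ey)[:, None] * psi)
        )
    return out


def drift(
    state: np.ndarray,
    model: ModelSpec,
    coeffs: MemoryCoefficients,
    ztilde: complex,
    *,
    t_index: int = -1,
    g1_bracket_factor: float = 2.0,
) -> np.ndarray:
    """Single-state drift evaluation at grid index ``t_index``.

    ``ztilde`` is the shifted noise value; its conjugate multiplies the
    fluctuation term.  Raises for non-finite states.
    """
    psi = np.asarray(state, dtype=complex)
    if not np.all(np.isfinite(psi)):
        raise ValueError("non-finite state passed to drift")
    ops = _DriftOperators(model)
    g0 = complex(coeffs.g0[t_index])
    g1 = complex(coeffs.g1[t_index])
    out = _drift_batch(ops, psi[None, :], np.array([np.conj(ztilde)]), g0, g1, g1_bracket_factor)
    return out[0]


def _trapezoid_shift(
    alpha: np.ndarray, hist: np.ndarray, dt: float, m: int
) -> np.ndarray:
    """int_0^{t_m} alpha(t_m - s) hist(s) ds by trapezoid on a uniform grid.

    ``hist`` is (B, >= m+1); returns a (B,) complex array.
    """
    if m == 0:
        return np.zeros(hist.shape[0], dtype=complex)
    w = np.full(m + 1, dt)
    w[0] *= 0.5
    w[-1] *= 0.5
    return hist[:, : m + 1] @ (w * alpha[m::-1])


def propagate_batch(
    model: ModelSpec,
    coeffs: MemoryCoefficients,
    z_paths: np.ndarray,
    config: IntegratorConfig,
    *,
    init_state: Optional[np.ndarray] = None,
    events: Optional[Sequence] = None,
    kick: Optional[KickOperator] = None,
    observer=None,
    store_states: bool = True,
):
    """Propagate a batch of trajectories sharing the model and grid.

    Parameters
    ----------
    z_paths
        (B, n_times) complex array of raw noise realizations on
        ``coeffs.t_grid``.
    events
        Optional per-trajectory ``EventStream`` sequence (length B); kicks
        are applied at event times between steps via ``kick``.
    observer
        Optional object with ``update(step_index, psi_batch)`` called with
        the normalized states after every step (and at t = 0).
    store_states
        When False the full state series is not kept (observer-driven use).

    Returns
    -------
    psi : (B, n_times, dim) array or None
    norms : (B, n_times) pre-normalization norms
    """
    config.validate_for(model)
    t = np.asarray(coeffs.t_grid, dtype=float)
    n_times = t.size
    dt = float(t[1] - t[0])
    if np.max(np.abs(np.diff(t) - dt)) > 1e-9 * dt:
        raise ValueError("propagation requires a uniform time grid")
    z = np.asarray(z_paths, dtype=complex)
    if z.ndim != 2 or z.shape[1] != n_times:
        raise ValueError("z_paths must be (B, n_times) on the coefficient grid")
    bsize = z.shape[0]
    if events is not None and len(events) != bsize:
        raise ValueError("events must have one stream per trajectory")
    if events is not None and any(len(ev) for ev in events) and kick is None:
        raise ValueError("events supplied but no kick operator given")

    ops = _DriftOperators(model)
    psi0 = donor_vacuum_state(model) if init_state is None else np.asarray(init_state, complex)
    psi = np.tile(psi0 / np.linalg.norm(psi0), (bsize, 1))

    alpha = coeffs.kernel.at(t - t[0]) if coeffs.kernel is not None else None
    g0 = np.asarray(coeffs.g0, dtype=complex)
    g1 = np.asarray(coeffs.g1, dtype=complex)
    fac = config.g1_bracket_factor

    # per-step event bucketing: events in (t_n, t_{n+1}] applied after step n
    step_events: list[list[tuple[int, float]]] = [[] for _ in range(n_times)]
    if events is not None:
        for b, ev in enumerate(events):
            if len(ev) == 0:
                continue
            idx = np.clip(np.ceil(ev.times / dt - 1e-12).astype(int), 1, n_times - 1)
            for i, a in zip(idx, ev.marks):
                step_events[i].append((b, float(a)))

    hist = np.zeros((bsize, n_times))  # <L^dagger> history (real for L ~ sigma_z)
    hist[:, 0] = ops.gamma * _expect(psi, psi @ ops.szT, np.ones(bsize)).real

    out_psi = np.empty((bsize, n_times, model.dim), dtype=complex) if store_states else None
    norms = np.ones((bsize, n_times))
    if store_states:
        out_psi[:, 0] = psi
    if observer is not None:
        observer.update(0, psi)

    def _shift(m: int, hist_arr: np.ndarray) -> np.ndarray:
        if alpha is None or ops.gamma == 0.0:
            return np.zeros(bsize, dtype=complex)
        return _trapezoid_shift(alpha, hist_arr, dt, m)

    half_uT = None
    if config.scheme == "splitting":
        from scipy.linalg import expm

        half_uT = expm(-0.5j * dt * ops.h).T.copy()

    def _close_shift(pred: np.ndarray, n: int) -> np.ndarray:
        """Predictor expectation closes the shift integral at t_{n+1}."""
        pred_norm2 = np.einsum("bi,bi->b", pred.conj(), pred).real
        hist[:, n + 1] = ops.gamma * _expect(pred, pred @ ops.szT, pred_norm2).real
        return np.conj(z[:, n + 1] + _shift(n + 1, hist))

    shift_n = _shift(0, hist)
    for n in range(n_times - 1):
        zeta_n = np.conj(z[:, n] + shift_n)

        if config.scheme == "splitting":
            # Strang split: exact Hamiltonian half-steps around a Heun
            # update of the (non-stiff) bath terms
            psi_a = psi @ half_uT
            s1 = _drift_batch(ops, psi_a, zeta_n, g0[n], g1[n], fac, include_h=False)
            zeta_np1 = _close_shift((psi_a + dt * s1) @ half_uT, n)
            s2 = _drift_batch(
                ops, psi_a + dt * s1, zeta_np1, g0[n + 1], g1[n + 1], fac, include_h=False
            )
            new = (psi_a + 0.5 * dt * (s1 + s2)) @ half_uT
        elif config.scheme == "heun":
            k1 = _drift_batch(ops, psi, zeta_n, g0[n], g1[n], fac)
            zeta_np1 = _close_shift(psi + dt * k1, n)
            k2 = _drift_batch(ops, psi + dt * k1, zeta_np1, g0[n + 1], g1[n + 1], fac)
            new = psi + 0.5 * dt * (k1 + k2)
        else:  # rk4, noise interpolated linearly to the half step
            k1 = _drift_batch(ops, psi, zeta_n, g0[n], g1[n], fac)
            zeta_np1 = _close_shift(psi + dt * k1, n)
            zeta_h = 0.5 * (zeta_n + zeta_np1)
            g0h = 0.5 * (g0[n] + g0[n + 1])
            g1h = 0.5 * (g1[n] + g1[n + 1])
            k2 = _drift_batch(ops, psi + 0.5 * dt * k1, zeta_h, g0h, g1h, fac)
            k3 = _drift_batch(ops, psi + 0.5 * dt * k2, zeta_h, g0h, g1h, fac)
            k4 = _drift_batch(ops, psi + dt * k3, zeta_np1, g0[n + 1], g1[n + 1], fac)
            new = psi + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)

        step_norm = np.linalg.norm(new, axis=1)
        if np.any(step_norm < _NORM_FLOOR):
            bad = int(np.argmin(step_norm))
            raise FloatingPointError(
                f"norm collapse in trajectory {bad} at step {n + 1} "
                f"(|psi| = {step_norm[bad]:.3e})"
            )
        norms[:, n + 1] = step_norm
        if (n + 1) % config.renormalize_every == 0:
            new = new / step_norm[:, None]

        for b, a in step_events[n + 1]:
            new[b] = kick.apply(new[b], a)

        psi = new
        norm2 = np.einsum("bi,bi->b", psi.conj(), psi).real
        hist[:, n + 1] = ops.gamma * _expect(psi, psi @ ops.szT, norm2).real
        shift_n = _shift(n + 1, hist)

        if store_states:
            out_psi[:, n + 1] = psi / np.linalg.norm(psi, axis=1)[:, None]
        if observer is not None:
            observer.update(n + 1, psi / np.linalg.norm(psi, axis=1)[:, None])

    return out_psi, norms


def propagate_trajectory(
    model: ModelSpec,
    coeffs: MemoryCoefficients,
    path: NoisePath,
    config: IntegratorConfig,
    *,
    init_state: Optional[np.ndarray] = None,
    kick: Optional[KickOperator] = None,
) -> TrajectoryResult:
    """Propagate one normalized trajectory driven by ``path``.

    Kicks are taken from the path's own event stream when present (the
    stream that generated the noise also triggers the jumps).
    """
    events = None
    if path.events is not None and len(path.events):
        events = [path.events]
        if kick is None:
            kick = KickOperator(model)
    psi, norms = propagate_batch(
        model,
        coeffs,
        path.z[None, :],
        config,
        init_state=init_state,
        events=events,
        kick=kick,
        store_states=True,
    )
    return TrajectoryResult(
        t_grid=np.asarray(coeffs.t_grid, dtype=float),
        psi=psi[0],
        norms=norms[0],
        seed=path.seed,
    )
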