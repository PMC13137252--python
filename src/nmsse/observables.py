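"""Ensemble averaging and the transfer observables.

The reduced density matrix is the trajectory average
rho(t) = M[|psi~_t><psi~_t|]; donor/acceptor populations come from the
electronic-block partial trace, the electronic coherence from the
off-diagonal block, and the vibrational occupation from Tr[rho (I x n)].
The headline scalar is the vibronic enhancement

    DeltaP = max_t P_DA(t)|with vib - max_t P_DA(t)|without vib,

mapped over electronic coupling, vibronic coupling and bath statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .integrator import TrajectoryResult
from .model import ModelSpec

__all__ = [
    "EnsembleResult",
    "EnsembleAccumulator",
    "ensemble_density",
    "transfer_probability_max",
    "delta_p",
    "vibrational_energy_series",
    "ScanResult",
    "scan_map",
]


@dataclass(frozen=True)
class EnsembleResult:
    """Ensemble-averaged reduced dynamics with Monte-Carlo standard errors."""

    t_grid: np.ndarray
    rho: np.ndarray  # (n_times, dim, dim)
    p_donor: np.ndarray
    p_acceptor: np.ndarray
    coherence_abs: np.ndarray
    n_vib: Optional[np.ndarray]
    se_p_acceptor: np.ndarray
    n_traj: int
    master_seed: Optional[int] = None
    model: Optional[ModelSpec] = None

    def to_frame(self):
        """Time-series export (t, P_D, P_A, Re/Im rho_DA, n_vib, se_P_A)."""
        import pandas as pd

        nf = self.rho.shape[1] // 2
        rho_da = np.einsum("tnn->t", self.rho[:, :nf, nf:])
        data = {
            "t": self.t_grid,
            "P_D": self.p_donor,
            "P_A": self.p_acceptor,
            "Re_rho_DA": rho_da.real,
            "Im_rho_DA": rho_da.imag,
            "n_vib": self.n_vib if self.n_vib is not None else np.nan,
            "se_P_A": self.se_p_acceptor,
        }
        return pd.DataFrame(data)


class EnsembleAccumulator:
    """Streaming accumulator for chunked ensemble propagation.

    Feed normalized state batches step-by-step via :meth:`update` (matching
    the integrator's observer protocol), or whole (B, T, dim) blocks via
    :meth:`add_states`; call :meth:`finalize` once all trajectories are in.
    """

    def __init__(self, model: ModelSpec, t_grid):
        self.model = model
        self.t_grid = np.asarray(t_grid, dtype=float)
        d = model.dim
        nt = self.t_grid.size
        self._rho_sum = np.zeros((nt, d, d), dtype=complex)
        self._pa_sum = np.zeros(nt)
        self._pa_sq_sum = np.zeros(nt)
        self._count_per_step = np.zeros(nt, dtype=np.int64)
        self._nfock = model.nfock

    def update(self, step: int, psi_batch: np.ndarray) -> None:
        psi = np.atleast_2d(psi_batch)
        self._rho_sum[step] += np.einsum("bi,bj->ij", psi, psi.conj())
        pa = np.einsum("bi,bi->b", psi[:, self._nfock :].conj(), psi[:, self._nfock :]).real
        self._pa_sum[step] += pa.sum()
        self._pa_sq_sum[step] += (pa**2).sum()
        self._count_per_step[step] += psi.shape[0]

    def add_states(self, psi_block: np.ndarray) -> None:
        """Add a (B, n_times, dim) block of normalized trajectories."""
        for step in range(psi_block.shape[1]):
            self.update(step, psi_block[:, step])

    def finalize(self, master_seed: Optional[int] = None) -> EnsembleResult:
        counts = np.unique(self._count_per_step)
        if counts.size != 1 or counts[0] < 1:
            raise ValueError("inconsistent or empty trajectory accumulation")
        n = int(counts[0])
        rho = self._rho_sum / n
        nf = self._nfock
        p_d = np.einsum("tnn->t", rho[:, :nf, :nf]).real
        p_a = np.einsum("tnn->t", rho[:, nf:, nf:]).real
        coh = np.abs(np.einsum("tnn->t", rho[:, :nf, nf:]))
        n_vib = None
        if self.model.vibronic is not None:
            occ = np.arange(nf, dtype=float)
            diag = np.einsum("tnn->tn", rho).real
            n_vib = diag[:, :nf] @ occ + diag[:, nf:] @ occ
        mean_pa = self._pa_sum / n
        if n > 1:
            var = (self._pa_sq_sum / n - mean_pa**2) * n / (n - 1)
            se = np.sqrt(np.clip(var, 0.0, None) / n)
        else:
            se = np.zeros_like(mean_pa)
        return EnsembleResult(
            t_grid=self.t_grid,
            rho=rho,
            p_donor=p_d,
            p_acceptor=p_a,
            coherence_abs=coh,
            n_vib=n_vib,
            se_p_acceptor=se,
            n_traj=n,
            master_seed=master_seed,
            model=self.model,
        )


def ensemble_density(
    trajectories: Sequence[TrajectoryResult],
    model: ModelSpec,
    *,
    master_seed: Optional[int] = None,
) -> EnsembleResult:
    """Average a stream of trajectories into the reduced density matrix.

    All trajectories must share a common time grid.
    """
    trajs = list(trajectories)
    if not trajs:
        raise ValueError("need at least one trajectory")
    t = trajs[0].t_grid
    acc = EnsembleAccumulator(model, t)
    for tr in trajs:
        if tr.t_grid.shape != t.shape or not np.allclose(tr.t_grid, t):
            raise ValueError("trajectories must share a common time grid")
        acc.add_states(tr.psi[None, :, :])
    return acc.finalize(master_seed=master_seed)


def transfer_probability_max(result: EnsembleResult) -> float:
    """Maximum acceptor population over the simulated window."""
    if result.p_acceptor.size == 0:
        raise ValueError("empty ensemble series")
    return float(result.p_acceptor.max())


def delta_p(with_vib: EnsembleResult, without_vib: EnsembleResult) -> float:
    """Vibronic transfer enhancement DeltaP = maxP(with) - maxP(without)."""
    if with_vib.t_grid.shape != without_vib.t_grid.shape or not np.allclose(
        with_vib.t_grid, without_vib.t_grid
    ):
        raise ValueError("ensembles must share the same time window and grid")
    return transfer_probability_max(with_vib) - transfer_probability_max(without_vib)


def vibrational_energy_series(result: EnsembleResult) -> np.ndarray:
    """Mean vibrational occupation <n>(t); requires a vibronic mode."""
    if result.n_vib is None:
        raise ValueError("ensemble was computed for a model without a vibronic mode")
    return result.n_vib


@dataclass(frozen=True)
class ScanResult:
    """Long-format DeltaP map over the scanned axes, with MC errors and
    regime labels derived from Lambda."""

    table: "object"  # pandas DataFrame
    axes: dict
    metadata: dict


def scan_map(*args, **kwargs) -> ScanResult:
    """Two-dimensional DeltaP regime map; see :func:`nmsse.simulate.scan_map`."""
    from .simulate import scan_map as _impl

    return _impl(*args, **kwargs)
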