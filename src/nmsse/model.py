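"""System Hamiltonians and closed-system reference dynamics.

The receptor is a two-level donor/acceptor dimer,

.. math:: H_R = \\tfrac{\\epsilon}{2}\\sigma_z + \\tfrac{\\Delta}{2}\\sigma_x,

with energy bias ``epsilon`` = eps_D - eps_A and tunnelling coupling
``Delta``.  The ligand contributes one discrete vibrational mode of quantum
``omega`` coupled to the electronic states through sigma_z, giving the
vibronic system Hamiltonian

.. math::
    H_S = \\tfrac{\\epsilon}{2}\\sigma_z + \\tfrac{\\Delta}{2}\\sigma_x
        + \\omega(b^\\dagger b + \\tfrac12)
        + \\sigma_z\\,\\omega\\gamma\\,(b + b^\\dagger)

on a Fock-truncated tensor-product space.

Unit conventions (owned by this module): hbar = 1, energies in eV, time in
1/eV (1 eV^-1 ~ 0.658 fs).  Basis ordering is electronic index slow, Fock
index fast; the donor state |D> is the sigma_z eigenvector with eigenvalue
+1 (index 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "HC_EV_CM",
    "EV_INV_FS",
    "SIGMA_X",
    "SIGMA_Y",
    "SIGMA_Z",
    "DimerSpec",
    "VibronicSpec",
    "ModelSpec",
    "wavenumber_to_ev",
    "destroy_operator",
    "build_receptor_hamiltonian",
    "build_system_hamiltonian",
    "electronic_operator",
    "vibrational_operator",
    "donor_vacuum_state",
    "effective_frequency",
    "rabi_max_probability",
    "closed_population",
]

#: hc in eV*cm (CODATA): 1 cm^-1 corresponds to 1.2398419e-4 eV.
HC_EV_CM = 1.239841984e-4

#: One inverse electron-volt of time expressed in femtoseconds (hbar/eV).
EV_INV_FS = 0.6582119569

SIGMA_X = np.array([[0.0, 1.0], [1.0, 0.0]], dtype=complex)
SIGMA_Y = np.array([[0.0, -1.0j], [1.0j, 0.0]], dtype=complex)
SIGMA_Z = np.array([[1.0, 0.0], [0.0, -1.0]], dtype=complex)


def wavenumber_to_ev(value):
    """Convert a wavenumber in cm^-1 to an energy in eV.

    Exact linear map ``value * hc`` with hc in eV*cm; the sign passes
    through, so negative detunings are allowed.
    """
    return np.asarray(value, dtype=float) * HC_EV_CM if np.ndim(value) else float(value) * HC_EV_CM


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class DimerSpec:
    """Two-level donor/acceptor dimer parameters (eV).

    ``epsilon`` is the donor-acceptor energy bias eps_D - eps_A and
    ``delta`` the tunnelling coupling; ``delta`` must be nonnegative.
    """

    epsilon: float
    delta: float

    def __post_init__(self):
        _require_finite("epsilon", self.epsilon)
        _require_finite("delta", self.delta)
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")


@dataclass(frozen=True)
class VibronicSpec:
    """Discrete vibrational mode: quantum ``omega`` (eV), dimensionless
    coupling (the coupling energy is ``omega * coupling``) and Fock
    truncation ``fock_cutoff`` = N (Hilbert dimension N + 1)."""

    omega: float
    coupling: float
    fock_cutoff: int = 10

    def __post_init__(self):
        _require_finite("omega", self.omega)
        _require_finite("coupling", self.coupling)
        if self.omega <= 0:
            raise ValueError(f"omega must be > 0, got {self.omega}")
        if int(self.fock_cutoff) < 1:
            raise ValueError(f"fock_cutoff must be >= 1, got {self.fock_cutoff}")


@dataclass(frozen=True)
class ModelSpec:
    """Full system: dimer, optional vibronic mode, and the dimensionless
    system-bath coupling amplitude ``gamma_nj`` entering L = gamma_nj sigma_z."""

    dimer: DimerSpec
    vibronic: Optional[VibronicSpec] = None
    gamma_nj: float = 0.0

    def __post_init__(self):
        _require_finite("gamma_nj", self.gamma_nj)
        if self.gamma_nj < 0:
            raise ValueError(f"gamma_nj must be >= 0, got {self.gamma_nj}")

    @property
    def nfock(self) -> int:
        """Fock-space dimension (N + 1), or 1 when no mode is present."""
        return int(self.vibronic.fock_cutoff) + 1 if self.vibronic is not None else 1

    @property
    def dim(self) -> int:
        """Total Hilbert-space dimension 2 * (N + 1)."""
        return 2 * self.nfock


def destroy_operator(nfock: int) -> np.ndarray:
    """Truncated bosonic annihilation operator b on ``nfock`` Fock states."""
    return np.diag(np.sqrt(np.arange(1, nfock, dtype=float)), k=1).astype(complex)


def build_receptor_hamiltonian(dimer: DimerSpec) -> np.ndarray:
    """(epsilon/2) sigma_z + (Delta/2) sigma_x in the {|D>, |A>} basis.

    Hermitian and traceless; eigenvalues are +/- Omega/2 with
    Omega = sqrt(epsilon^2 + Delta^2).
    """
    return 0.5 * dimer.epsilon * SIGMA_Z + 0.5 * dimer.delta * SIGMA_X


def electronic_operator(op: np.ndarray, model: ModelSpec) -> np.ndarray:
    """Lift a 2x2 electronic operator to the full space (identity on Fock)."""
    if model.vibronic is None:
        return np.asarray(op, dtype=complex)
    return np.kron(np.asarray(op, dtype=complex), np.eye(model.nfock, dtype=complex))


def vibrational_operator(op: np.ndarray, model: ModelSpec) -> np.ndarray:
    """Lift a Fock-space operator to the full space (identity on electronic)."""
    if model.vibronic is None:
        raise ValueError("model has no vibronic mode")
    return np.kron(np.eye(2, dtype=complex), np.asarray(op, dtype=complex))


def build_system_hamiltonian(model: ModelSpec) -> np.ndarray:
    """Full vibronic system Hamiltonian on the truncated product space.

    H = (eps/2) sigma_z + (Delta/2) sigma_x + omega (b'b + 1/2)
        + sigma_z * omega*gamma * (b + b').

    Falls back to the bare receptor Hamiltonian when the model carries no
    vibronic mode.
    """
    h_el = build_receptor_hamiltonian(model.dimer)
    if model.vibronic is None:
        return h_el
    vib = model.vibronic
    nf = model.nfock
    b = destroy_operator(nf)
    number = b.conj().T @ b
    x = b + b.conj().T
    h = np.kron(h_el, np.eye(nf, dtype=complex))
    h += np.kron(np.eye(2, dtype=complex), vib.omega * (number + 0.5 * np.eye(nf)))
    h += np.kron(SIGMA_Z, vib.omega * vib.coupling * x)
    return h


def donor_vacuum_state(model: ModelSpec) -> np.ndarray:
    """The default initial state |D> (x) |0>: donor site, vibrational vacuum."""
    psi = np.zeros(model.dim, dtype=complex)
    psi[0] = 1.0
    return psi


def effective_frequency(dimer: DimerSpec) -> float:
    """Intrinsic electronic frequency Omega = sqrt(epsilon^2 + Delta^2)."""
    return math.hypot(dimer.epsilon, dimer.delta)


def rabi_max_probability(dimer: DimerSpec) -> float:
    """Maximum donor->acceptor transfer probability of the isolated dimer,
    Delta^2 / (Delta^2 + epsilon^2).

    Raises ``ValueError`` for the degenerate Omega = 0 dimer, where no
    transfer dynamics is defined.
    """
    omega2 = dimer.delta**2 + dimer.epsilon**2
    if omega2 == 0.0:
        raise ValueError("rabi_max_probability undefined for epsilon = delta = 0")
    return dimer.delta**2 / omega2


def closed_population(t, dimer: DimerSpec):
    """Acceptor population of the isolated dimer started in |D>:
    P(t) = (Delta^2/Omega^2) sin^2(Omega t / 2).  Vectorized in ``t``."""
    t = np.asarray(t, dtype=float)
    omega = effective_frequency(dimer)
    if omega == 0.0:
        return np.zeros_like(t) if t.ndim else 0.0
    p = (dimer.delta**2 / omega**2) * np.sin(0.5 * omega * t) ** 2
    return p if t.ndim else float(p)
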