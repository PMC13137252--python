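"""Independent reference implementations used only as test oracles.

Nothing here imports the integrator under test: the master-equation solver
is a plain density-matrix ODE, the closed-system propagator uses dense
matrix exponentials, and quadratures are brute-force Riemann sums.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

SX = np.array([[0, 1], [1, 0]], dtype=complex)
SY = np.array([[0, -1j], [1j, 0]], dtype=complex)
SZ = np.array([[1, 0], [0, -1]], dtype=complex)


def closed_two_level_population(t_grid, epsilon, delta):
    """Acceptor population by dense matrix-exponential propagation of the
    two-level Hamiltonian from the donor state."""
    h = 0.5 * epsilon * SZ + 0.5 * delta * SX
    psi0 = np.array([1.0, 0.0], dtype=complex)
    out = np.empty(len(t_grid))
    for i, t in enumerate(t_grid):
        psi = expm(-1j * h * t) @ psi0
        out[i] = abs(psi[1]) ** 2
    return out


def convolutionless_master_equation(t_grid, epsilon, delta, gamma, g0, g1):
    """Reduced dynamics of the dephasing-coupled dimer under the
    time-local convolutionless master equation

        drho/dt = -i[H, rho] + [L rho, Obar^+] + [Obar, rho L^+],

    with L = gamma sigma_z and the truncated memory operator
    Obar(t) = gamma (g0(t) sigma_z - i g1(t) Delta sigma_y).  ``g0``/``g1``
    are arrays sampled on ``t_grid``.  In the Markov limit g1 -> 0,
    g0 -> const this is the Lindblad dephasing equation with rate
    2 gamma^2 g0.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    h = 0.5 * epsilon * SZ + 0.5 * delta * SX
    ell = gamma * SZ

    def rhs(t, y):
        rho = y.reshape(2, 2)
        g0t = np.interp(t, t_grid, np.real(g0)) + 1j * np.interp(t, t_grid, np.imag(g0))
        g1t = np.interp(t, t_grid, np.real(g1)) + 1j * np.interp(t, t_grid, np.imag(g1))
        obar = gamma * (g0t * SZ - 1j * g1t * delta * SY)
        drho = -1j * (h @ rho - rho @ h)
        drho += ell @ rho @ obar.conj().T - obar.conj().T @ ell @ rho
        drho += obar @ rho @ ell.conj().T - rho @ ell.conj().T @ obar
        return drho.ravel()

    rho0 = np.zeros((2, 2), dtype=complex)
    rho0[0, 0] = 1.0
    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        rho0.ravel(),
        t_eval=t_grid,
        rtol=1e-10,
        atol=1e-12,
    )
    rho = sol.y.reshape(2, 2, -1)
    return rho[1, 1].real


def riemann_kernel_value(tau, mode_freqs, gamma, linewidth, kbt, cutoff, n=2_000_001):
    """Brute-force Riemann-sum evaluation of the finite-temperature bath
    kernel at a single lag (independent second quadrature scheme)."""
    w = np.linspace(0.0, cutoff, n)
    j = np.zeros_like(w)
    for wi in mode_freqs:
        j += gamma * linewidth * wi**2 * w / ((wi**2 - w**2) ** 2 + linewidth**2 * w**2)
    if kbt > 0:
        with np.errstate(divide="ignore", invalid="ignore"):
            weight = j / np.tanh(w / (2.0 * kbt))
        weight[0] = 2.0 * kbt * sum(gamma * linewidth / wi**2 for wi in mode_freqs)
    else:
        weight = j
    return np.trapezoid(weight * np.exp(-1j * w * tau), w)


def displaced_oscillator_levels(epsilon, omega, coupling, n_levels):
    """Exact polaron-shifted spectrum of the Delta = 0 vibronic Hamiltonian:
    per sigma_z branch s = +/-1, E_n = s eps/2 + omega (n + 1/2) - omega g^2."""
    shift = omega * coupling**2
    levels = []
    for s in (+1.0, -1.0):
        for n in range(n_levels):
            levels.append(s * epsilon / 2.0 + omega * (n + 0.5) - shift)
    return np.sort(levels)
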