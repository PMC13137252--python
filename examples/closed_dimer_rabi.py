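"""Coherent donor->acceptor oscillations of the isolated two-level dimer.

Builds the bare receptor Hamiltonian H = (eps/2) sigma_z + (Delta/2) sigma_x,
propagates it from the donor state and compares the maximum transfer
probability against the closed form Delta^2 / (Delta^2 + eps^2).
"""

import numpy as np

from nmsse import (
    DimerSpec,
    IntegratorConfig,
    ModelSpec,
    effective_frequency,
    rabi_max_probability,
    run_ensemble,
    transfer_probability_max,
)

for eps, delta in [(0.0, 0.001), (0.1487, 0.1), (0.1487, 0.01)]:
    dimer = DimerSpec(epsilon=eps, delta=delta)
    omega = effective_frequency(dimer)
    config = IntegratorConfig(dt=0.02 / omega, enforce_step_limit=False)
    result = run_ensemble(
        ModelSpec(dimer=dimer, gamma_nj=0.0), None, config,
        n_traj=1, master_seed=0, n_periods=1.1,
    )
    print(
        f"eps={eps:7.4f} eV  Delta={delta:6.4f} eV  Omega={omega:7.4f} eV  "
        f"max P_D->A: propagated {transfer_probability_max(result):.5f}  "
        f"closed form {rabi_max_probability(dimer):.5f}"
    )

print(
    "\nThe propagated maximum reproduces Delta^2/(Delta^2+eps^2): complete "
    "transfer at zero bias, strongly suppressed transfer once the "
    "donor-acceptor bias exceeds the tunnelling coupling."
)
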