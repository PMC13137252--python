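"""Variance-matched Gaussian versus shot-noise population dynamics.

Runs small trajectory ensembles of the vibronic dimer under (i) colored
circular Gaussian noise and (ii) a filtered compound-Poisson bath with the
same second cumulant, in the sparse-event regime Lambda = 0.1, and prints
the transfer maxima.  Deviations isolate the higher-order (non-Gaussian)
statistics of the event bath.
"""

import numpy as np

from nmsse import (
    DimerSpec,
    IntegratorConfig,
    MarkDistribution,
    ModelSpec,
    PoissonBathSpec,
    VibronicSpec,
    poisson_kernel,
    run_ensemble,
    variance_match,
)
from nmsse.simulate import default_time_grid

model = ModelSpec(
    dimer=DimerSpec(epsilon=0.1487, delta=0.001),
    vibronic=VibronicSpec(omega=0.1487, coupling=0.2, fock_cutoff=10),
    gamma_nj=0.05,
)
config = IntegratorConfig(dt=0.25)
t = default_time_grid(model, config.dt, n_periods=3.0)

kappa = 0.005  # inverse bath memory, eV -> tau_c = 200/eV
lam = 0.1  # events per correlation time: sparse, strongly anharmonic
alpha0 = 0.0913  # matched noise variance, eV^2
bath = variance_match(
    alpha0,
    PoissonBathSpec(rate=lam * kappa, marks=MarkDistribution("two_point"), filter_kappa=kappa),
)
kernel = poisson_kernel(t, bath)

n_traj = 400
res_poisson = run_ensemble(model, bath, config, n_traj, master_seed=7, t_grid=t, kernel=kernel)
res_gauss = run_ensemble(model, kernel, config, n_traj, master_seed=8, t_grid=t)

print(f"window: {t[-1]:.0f} /eV  ({t.size} steps), {n_traj} trajectories each")
print(f"Lambda = {lam}: mark amplitude a0 = {bath.marks.scale:.3f}")
print(f"max P_D->A  Gaussian bath : {res_gauss.p_acceptor.max():.5f} "
      f"(SE {res_gauss.se_p_acceptor.max():.5f})")
print(f"max P_D->A  shot-noise bath: {res_poisson.p_acceptor.max():.5f} "
      f"(SE {res_poisson.se_p_acceptor.max():.5f})")
print(f"final coherence |rho_DA|:  Gaussian {res_gauss.coherence_abs[-1]:.5f}  "
      f"Poisson {res_poisson.coherence_abs[-1]:.5f}")
print(
    "\nAt weak electronic coupling the sparse-event bath transfers more "
    "population than the variance-matched Gaussian bath: rare large kicks "
    "assist transfer in a way second-order statistics cannot capture."
)
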