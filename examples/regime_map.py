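"""A small DeltaP regime map: vibronic transfer enhancement over the
electronic-coupling axis for both bath kinds.

DeltaP = max_t P_DA (vibronic coupling on) - max_t P_DA (coupling zeroed,
mode retained).  Cells run matched ensemble pairs; shot-noise cells are
variance-matched to the structured Gaussian bath and labelled by the
event-per-memory regime.
"""

from nmsse import (
    DimerSpec,
    IntegratorConfig,
    MarkDistribution,
    ModelSpec,
    PoissonBathSpec,
    SpectralDensitySpec,
    ThermalSpec,
    VibronicSpec,
    scan_map,
    wavenumber_to_ev,
)

model = ModelSpec(
    dimer=DimerSpec(epsilon=0.1487, delta=0.001),
    vibronic=VibronicSpec(omega=0.1487, coupling=0.2, fock_cutoff=8),
    gamma_nj=0.05,
)
gaussian_bath = SpectralDensitySpec(
    mode_freqs=[wavenumber_to_ev(w) for w in (836, 1000, 1240, 1600)],
    gamma=0.1,
    linewidth=0.005,
)
poisson_bath = PoissonBathSpec(
    rate=0.005, marks=MarkDistribution("two_point"), filter_kappa=0.005
)

result = scan_map(
    model,
    IntegratorConfig(dt=0.25),
    n_traj=200,  # demonstration size; increase for publication-level errors
    master_seed=11,
    axes={"delta": [1e-3, 1e-2], "lam": [0.1, 10.0]},
    bath_kinds=("gaussian", "poisson"),
    gaussian_bath=gaussian_bath,
    poisson_bath=poisson_bath,
    thermal=ThermalSpec(0.025),
    n_periods=2.0,
)

cols = ["bath", "regime", "delta", "lam", "delta_p", "se", "max_p_with", "max_p_without"]
print(result.table[cols].to_string(index=False, float_format=lambda v: f"{v:.5f}"))
print(
    "\nDeltaP > 0 marks cells where the discrete vibrational mode assists "
    "transfer; comparing bath kinds row-by-row shows how event statistics "
    "reshape that assistance (columns carry the MC standard error)."
)
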