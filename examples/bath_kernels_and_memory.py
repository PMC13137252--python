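"""Bath correlation kernels and the time-local memory coefficients.

Evaluates the finite-temperature kernel of the structured four-band
spectral density (band centres 836/1000/1240/1600 cm^-1, linewidth 5 meV,
kBT = 25 meV), the variance-matched shot-noise kernel, and the g0/g1
memory coefficients both baths feed into the stochastic equation of
motion.
"""

import numpy as np

from nmsse import (
    MarkDistribution,
    PoissonBathSpec,
    SpectralDensitySpec,
    ThermalSpec,
    gaussian_kernel,
    memory_coefficients,
    poisson_kernel,
    second_jump_moment,
    thermal_occupation,
    variance_match,
    wavenumber_to_ev,
)

bath = SpectralDensitySpec(
    mode_freqs=[wavenumber_to_ev(w) for w in (836, 1000, 1240, 1600)],
    gamma=0.1,
    linewidth=0.005,
)
thermal = ThermalSpec(kbt=0.025)
t = np.arange(0.0, 421.0) * 0.25  # ~3 electronic periods, in 1/eV

kernel_g = gaussian_kernel(t, bath, thermal)
print(f"Gaussian bath:  alpha_G(0) = {kernel_g.at_zero:.5f} eV^2")
print(f"thermal occupation of a 0.1487 eV mode at kBT=25 meV: "
      f"{thermal_occupation(0.1487, thermal):.2e}  (deep quantum regime)")

# shot-noise bath matched to the Gaussian variance, one event per memory time
matched = variance_match(
    kernel_g,
    PoissonBathSpec(rate=0.005, marks=MarkDistribution("two_point"), filter_kappa=0.005),
)
kernel_p = poisson_kernel(t, matched)
print(
    f"matched shot noise: alpha_P(0) = {kernel_p.at_zero:.5f} eV^2, "
    f"mark scale a0 = {matched.marks.scale:.4f}, "
    f"second jump moment = {second_jump_moment(matched):.3e}"
)

for name, kern in [("Gaussian", kernel_g), ("Poisson", kernel_p)]:
    co = memory_coefficients(kern, t)
    print(
        f"{name:8s} g0(T) = {co.g0[-1]:+.4f}   g1(T) = {co.g1[-1]:+.4f}  "
        f"(complex, units eV^2 * (1/eV)^k)"
    )

print(
    "\nalpha(0) fixes the total noise variance both baths share after "
    "matching; g0 and g1 are the zeroth/first memory moments entering the "
    "time-local equation - equal variances, different memory shapes."
)
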