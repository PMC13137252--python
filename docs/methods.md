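# Methods

## Model

`nmsse` simulates donor→acceptor electron transfer (ET) in a
receptor–ligand complex as an open quantum system.  The system is a
spin–boson-type vibronic dimer

```
H_S = (ε/2) σ_z + (Δ/2) σ_x + ω (b†b + 1/2) + σ_z ω γ_vib (b + b†)
```

with donor–acceptor energy bias ε = ε_D − ε_A, tunnelling coupling Δ, one
discrete vibrational mode of quantum ω truncated at N Fock states, and a
dimensionless vibronic coupling γ_vib (coupling energy ω·γ_vib).  Units are
ħ = 1 with all energies in eV and time in eV⁻¹ (1 eV⁻¹ ≈ 0.658 fs); the
donor state |D⟩ is the σ_z eigenvector with eigenvalue +1, basis ordering
is electronic-slow / Fock-fast.  The isolated dimer obeys the textbook
Rabi result max_t P_{D→A} = Δ²/(Δ² + ε²), which anchors several tests.

The environment couples through the Hermitian dephasing-type operator
L = γ_nj σ_z and is treated at the trajectory level with a non-Markovian
stochastic Schrödinger equation (NMSSE): normalized states ψ̃_t driven by
a colored c-number process z_t whose two-time correlation equals the bath
kernel α(t−s).  The memory enters through the truncated time-local
expansion of the functional-derivative operator, i.e. through

```
g0(t) = ∫₀ᵗ α(u) du,    g1(t) = ∫₀ᵗ u α(u) du,
```

and the simulated drift is (operators act on the electronic factor)

```
dψ̃/dt = −i H_S ψ̃
         + γ_nj (σ_z − ⟨σ_z⟩) ψ̃ · conj(z̃_t)
         − g0(t) γ_nj² [ (σ_z − ⟨σ_z⟩) σ_z − ⟨(σ_z − ⟨σ_z⟩) σ_z⟩ ] ψ̃
         + i g1(t) γ_nj² Δ [ (σ_z − ⟨σ_z⟩) σ_y − f ⟨(σ_z − ⟨σ_z⟩) σ_y⟩ ] ψ̃
```

with the Girsanov-shifted noise z̃_t = z_t + ∫₀ᵗ α(t−s) ⟨L†⟩_s ds using the
trajectory's own causal expectation history.  The bracket factor `f`
defaults to 2, and the explicit `i` prefactor of the g1 term is part of
the adopted equation convention; both are configurable
(`IntegratorConfig.g1_bracket_factor`).  A g2 coefficient (nested double
integral of the kernel) is implemented at the kernel level but is inert in
the dynamics: for Hermitian L its operator factor carries [L†, L] = 0.
The reduced density matrix is the ensemble mean ρ(t) = M[|ψ̃⟩⟨ψ̃|];
populations come from the electronic-block partial trace, so
P_D + P_A = 1 holds exactly.

## Baths

**Harmonic (Gaussian).**  A structured spectral density of narrow bands,
J(ω) = Σ_i γΓ ω_i² ω / [(ω_i² − ω²)² + Γ²ω²], with finite-temperature
kernel α_G(τ) = ∫₀^∞ J(ω) coth(ω/2k_BT) [cos ωτ − i sin ωτ] dω.  Two
integrand conventions are provided (`kernel_form`): `"full_coth"` (default)
multiplies coth into both quadratures; `"standard"` uses
coth·cos − i·sin.  The quadrature runs to 10× the largest band centre on a
uniform Simpson grid that is doubled until successive estimates agree to
1e−7 (sup-norm, relative); non-convergence raises with diagnostics.
Trajectory noise is circularly-symmetric complex colored Gaussian
(E[z_t z_s*] = α_G, E[z_t z_s] = 0), synthesized by eigendecomposition of
the Hermitian covariance matrix on the grid, with eigenvalues in
[−1e−10·λ_max, 0) clipped to zero and anything lower treated as an error.

**Anharmonic (compound-Poisson / shot-noise).**  Discrete events at rate
λ_p with i.i.d. mark amplitudes a (default family: symmetric two-point
±a₀; zero-mean Gaussian and degenerate "fixed" marks are available),
filtered through the causal response φ(u) = e^{−κu} cos(ω_P u) and
compensated to zero mean.  The second-cumulant kernel ansatz is
α_P(τ) = A₀ e^{−κ|τ|} cos(ω_P τ) with correlation time τ_c = κ⁻¹; for the
pure exponential filter (ω_P = 0) the ansatz coincides exactly with the
filtered process' stationary covariance, A₀ = λ_p E[a²]/(2κ).  For
ω_P > 0 the filter amplitude is rescaled so that the realized stationary
variance equals A₀ exactly, while the covariance *shape* then deviates
from the ansatz at relative order κ/ω_P (≈ 3% at the canonical κ = 5 meV,
ω_P = 0.1487 eV); the memory coefficients for shot-noise runs use the
ansatz kernel.  Variance matching against a Gaussian bath sets
A₀ = Re α_G(0) and rescales the marks so λ_p E[a²] = 2κA₀, leaving λ_p
free: the event-per-memory parameter Λ = λ_p τ_c can be scanned at fixed
noise variance, which isolates higher-order (non-Gaussian) statistics.

Three conventions make the variance-matched comparison well-posed; all
three are deliberate design choices of this package:

1. *Circular noise channel.*  Event marks carry i.i.d. uniform phases in
   the filtered noise (E[z z*] = α_P unchanged, E[z z] = 0).  A real
   process and a circular one differ at the level of the pseudo-covariance
   E[zz], and the nonlinear NMSSE responds to that difference at O(1); with
   phases, the compound-Poisson process converges (central limit) to
   exactly the circular Gaussian ensemble used for the harmonic bath, so
   Λ → ∞ recovers the Gaussian prediction.  Kick amplitudes and the
   cumulant diagnostics of the unfiltered compensated increments
   (κ_n[dX] = λ_p E[a^n] dt) use the real marks.
2. *Stationary burn-in.*  Ensemble runs sample events from −8/κ onward so
   the filtered process is stationary at t = 0, matching the stationary
   Gaussian sampler; only in-window events trigger kicks (the system state
   is prepared at t = 0).
3. *Coupling-scaled kicks.*  Each in-window event additionally applies the
   unitary kick U(a) = exp(−i s·a K) with generator K = σ_z ⊗ (b + b†),
   sharing the event stream with the noise.  At ensemble level the kick
   angle scale s defaults to γ_nj (the same amplitude that scales the
   noise channel).  With s = 1 the cumulative kick heating rate
   λ_p E[a²] = 2κA₀ would be Λ-independent and the shot-noise bath would
   never reduce to the Gaussian one; with s = γ_nj the heating is
   γ_nj²-suppressed and the weak-anharmonicity limit behaves as intended.
   The operator-level API (`kick_unitary`) keeps scale 1, so a kick of
   mark a on |D, 0⟩ raises ⟨n⟩ by exactly a².

## Integration

The default scheme (`"splitting"`) is a Strang split: exact Hamiltonian
half-steps with precomputed exp(−iH_S dt/2) around a stochastic-Heun
(predictor–corrector) update of the bath terms, renormalizing after every
step.  The split matters because the truncated Fock ladder carries level
spacings up to ω(N + ½) ≈ 1.6 eV at the defaults; explicit schemes on the
unsplit equation under-resolve those phases at practical steps and
artificially damp vibrational occupation.  Plain `"heun"` and `"rk4"` on
the unsplit equation are provided and tested for cross-checks.  All
schemes treat the colored noise as smooth within a step, which requires
dt ≪ τ_c; the step guard dt·Ω ≤ 0.05 is enforced by default.  The noise
shift integral and the g_i use consistent cumulative quadrature on the
propagation grid (Simpson for g_i, trapezoid for the causal shift).

Two error sources are worth keeping apart when validating against
time-local master-equation references: the smooth-noise treatment biases
ensembles when the kernel's cusp at τ = 0 is marginally resolved (κ·dt
not small), and the g0/g1 truncation itself carries an error that grows
with Ω/κ at fixed coupling and is independent of dt.  The test suite's
Markov-limit cross-check is therefore run deep in the Markov regime
(Ω/κ ≈ 0.09, κ·dt = 0.05), where the trajectory ensemble agrees with an
independent master-equation solve within Monte-Carlo error at n = 2000.

## Canonical parameterization and study conditions

Defaults follow the canonical ET setting: ε = 0.1487 eV (≈ 1199 cm⁻¹;
ε = ε_D − ε_A sign convention, with a `negate_epsilon` config flag),
Δ ∈ {10⁻⁴ … 10⁻¹} eV, four spectral bands at 836/1000/1240/1600 cm⁻¹,
linewidth Γ = 5 meV (τ_c = 200 eV⁻¹), k_BT = 25 meV, discrete mode
ω = 0.1487 eV with Fock cutoff N = 10, vibronic coupling γ_vib = 0.2
(mid-range of the 0–0.49 scan window), system–bath amplitude γ_nj = 0.02
(mid-range of 0.005–0.05), spectral coupling γ = 0.1 eV, ω_P defaulting
to the discrete-mode frequency, and Λ ∈ {0.1, 1, 10} for regime scans.
These give the dimensionless regime numbers ħω/k_BT ≈ 5.95,
n_th ≈ 2.6×10⁻³, Ω ≈ 0.149–0.179 eV, η_NM = Ω·τ_c ≈ 30–36: strongly
quantized vibrations and long bath memory.  Ensemble size defaults to
2000 trajectories with per-trajectory seeds spawned from a master seed by
a counter-based scheme; Monte-Carlo standard errors are attached to all
ensemble observables.  Default simulation windows cover a fixed number of
Rabi periods (10 for production runs; the test suite and examples use 3
periods and 300–2000 trajectories, sizes chosen so every statistical
check retains ≥3σ resolution).

## What the generator emulates — and what it does not

The synthetic configurations reproduce the *study conditions*: a single
discrete mode, a four-band structured bath, and an exponential-memory
event bath.  They do not emulate multi-mode vibronic manifolds, genuinely
anharmonic (Morse-like) environment propagation — the shot-noise bath is
the deliberate effective replacement for it — temperature-dependent
non-Condon effects, or any system-specific protein parameterization.
Passing tests therefore demonstrate internal consistency of the method
under the stated statistics (correct kernels, cumulants, limits, and
regime phenomenology), not agreement with measured ET kinetics of any
real complex.

## Degenerate inputs, tolerances, tie-breaks

Ω = 0 (ε = Δ = 0) makes the transfer maximum undefined and raises;
k_BT = 0 selects coth → 1 and n_th = 0 by convention; λ_p = 0 yields an
empty event stream and a zero path, and variance matching to a nonzero
target then raises.  Norm collapse below 1e−12 aborts a trajectory with
diagnostics.  Kernel covariance indefiniteness beyond 1e−10·λ_max is an
error rather than silently clipped.  `transfer_probability_max` takes the
maximum over the sampled grid; windows should cover at least one Rabi
period of the slowest dimer on a scan (the default window logic does).

## Known limitations

* The g0/g1 truncation is perturbative in the memory expansion: accuracy
  degrades as η_NM grows at fixed coupling, and no hierarchy (HOPS-style)
  closure is attempted.
* The ω_P > 0 ansatz kernel and the realized filtered covariance differ
  at O(κ/ω_P); comparisons that must be exact at second order should use
  ω_P = 0 (as the property suite does).
* ΔP maps inherit Monte-Carlo noise of order n_traj^{−1/2}; cells report
  standard errors, and maxima over time of noisy means carry a small
  upward bias common to both baths.
* The event bath's kick generator and scale are model choices (see above),
  not derived from a microscopic anharmonic surface.
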