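# Methods

## Model

An n-level quantum subsystem (Hamiltonian H_S, Hermitian) is bilinearly
coupled to two banks of harmonic modes treated semi-classically: "phonon"
modes (R_J, P_J) coupled through a dimensionless Hermitian operator χ with
constants C_J, and "electromagnetic-field" modes (Q_K, Π_K) coupled through
ζ with constants F_K.  After a partial Wigner transform over the mode
coordinates, operators become mixed Weyl symbols — Hermitian-matrix-valued
functions of the classical phase point — and the Hamiltonian symbol is

    H(X, Y) = H_S + Σ_J (P_J² + ω_J²R_J²)/2 · I + Σ_K (Π_K² + ω_K²Q_K²)/2 · I
                  − Σ_J C_J R_J χ − Σ_K F_K Q_K ζ.

Units: ħ = k_B = 1 and unit (mass-weighted) mode masses, so kinetic terms
read P²/2 and every frequency/energy is dimensionless.  The two banks are
structurally identical and share one implementation, distinguished only by
their coupling operator.  H_S is time-independent on the tested paths; the
symbol container admits time-dependent generalizations but none are wired
into the solvers.

Time evolution is generated by the quantum–classical bracket

    ∂_t O = i[H, O] − ½(∂_R H ∂_P O − ∂_P H ∂_R O) + ½(∂_R O ∂_P H − ∂_P O ∂_R H)

(Heisenberg picture; all products are matrix products, derivatives run over
all mode coordinates).  Statistical symbols W evolve with the opposite
overall sign (Schrödinger picture); the two pictures are dual under the
trace functional Tr′∫dX W O, and that duality is asserted in the tests.
The bracket is exact for a harmonic bank bilinearly coupled to the
subsystem when the coupling commutes with H_S (pure dephasing), which is
why that model serves as an end-to-end oracle.

## Thermal and zero-point statistics

The thermal Wigner function of a mode (β, ω) is Gaussian with

    <P²> = ω / (2 tanh(βω/2)) = 1/β_eff,    <R²> = <P²>/ω²,
    β_eff(β, ω) = 2 tanh(βω/2)/ω.

β_eff → β in the classical limit βω → 0 and → 2/ω at T = 0 (zero-point
energy ω/4 per quadrature).  T = 0 is represented by an explicit
`beta = inf` flag, never by a large float.  Each mode's weight is
normalized to unit integral over (R, P); the prefactor in these units is
tanh(βω/2)/π.  This normalization is forced by the role of W as a
probability weight in averages.  Initial conditions are drawn mode-by-mode
from these Gaussians with a seeded generator; chain variables start at
exactly zero (delta-function factors in the extended-space weight).  The
subsystem factor w_S is a user-supplied density matrix (Hermitian, unit
trace, PSD), defaulting to the ground state of H_S.

## Nosé–Hoover chain thermostats

Each mode I carries its own chain (η_L, P_ηL), L = 1..M (default M = 2),
with extended Hamiltonian

    H_e = H(X) + Σ_IL P_ηL²/(2 M_ηL) + Σ_IL T(I) η_L.

The flow is dX_e/dt = B(X_e) ∇H_e with an exactly antisymmetric structure
matrix B: symplectic pairing on the physical sector, each mode momentum
coupled to its first chain link (friction −P·P_η1/M_1), successive links
coupled through P_ηL feedback.  Antisymmetry makes H_e a constant of
motion; a sympy computer-algebra test expands B∇H_e symbolically and
matches the explicit equations of motion.  The chain kinetic term carries
the standard factor ½ so that this product reproduces textbook NHC
equations.

Setting T(I) = 1/β_eff(β, ω_I) makes the mode's stationary kinetic moment
equal the quantum Wigner variance — thermal at finite β, zero-point ω/2 at
β = ∞; setting T(I) = T gives ordinary canonical sampling.

Integration is a reversible Trotter splitting: half-step chain updates
(7-point Suzuki–Yoshida composition of the standard chain sweep,
momentum-rescale included) around velocity Verlet on the physical mode.
An optional 4th-order Yoshida composition of the whole step serves
high-accuracy conservation checks.  Default chain masses are M_η = T(I)/ω_I²
(chain responding on the mode's own period), which in practice makes a
single stiff harmonic mode ergodic enough that 2% kinetic-moment accuracy
is reached in ~10³ mode periods.  Chain momenta are guarded at 1e8;
exceeding the guard (or any non-finite value) aborts with a "reduce dt"
diagnostic rather than propagating NaNs.

## Grid solver (reference)

For one classical mode and small n, W (or O) is discretized on a
rectangular (R, P) lattice.  Phase-space derivatives are 4th-order central
finite differences on a *periodic* stencil: one-sided boundary closures
proved weakly unstable over long advection runs, while the periodic wrap is
benign because states are required to keep boundary mass below 1e-8 of the
total (checked, flagged as a warning) and phase-space-uniform observable
fields remain exactly uniform.  Time stepping is RK4 with re-Hermitization
each step; dt above a stability estimate (advection rates plus the largest
local eigenvalue spread, against the RK4 imaginary-axis limit) is rejected
with a suggested value.  Grid extents default to ±6 thermal widths plus any
requested shift toward displaced surface minima; the trace functional must
stay within 1e-6 over a run or the propagation errors out.

Benchmarks: decoupled Rabi oscillation (error ~1e-10 over ten periods at
dt = 0.002), classical Liouville rotation of a displaced Gaussian, and
pure dephasing against a numerically exact quantized-oscillator reference
(coherence modulus to ~5e-6 on a 128² grid).

## Trajectory solver (production)

Sequential short-time propagation in the adiabatic basis of
h(R) = H_S − Σ_J C_J R_J χ (the classical scalar part shifts all surfaces
equally and is handled analytically).  Each ensemble member carries a phase
point sampled from the Wigner weight, an index pair (a, b) drawn uniformly
from the n² pairs, and a complex coefficient.  Its statistical factor is
n² (U₀ᴴ w_S U₀)_{b a} at the initial point, so the ensemble mean of
factor × coeff × O^{adiab}_{a_t b_t}(X_t) estimates ⟨O(t)⟩; standard errors
are reported from the member scatter.

Per step of size dt:

1. phase: coeff ×= exp(i (E_a − E_b) dt/2), repeated after the move;
2. classical move: velocity Verlet on the mean surface force
   −½(∇E_a + ∇E_b) (Hellmann–Feynman), with optional NHC half-steps;
3. hops (nonadiabatic mode): for each index independently, the transition
   strength to each partner is g = P·d with derivative coupling
   d_{aa'} = ⟨a|∂H/∂R|a'⟩/(E_{a'} − E_a); channels whose momentum jump
   would be imaginary are excluded up front (naive frustrated-hop fallback
   measurably biases the estimator); a hop fires with probability
   g_tot dt/(1 + g_tot dt), multiplies the weight by the signed factor
   sgn(g)(1 + g_tot dt) (declined: 1 + g_tot dt), and shifts the momentum
   along d̂ so the kinetic energy covers the half-gap change of the mean
   surface.

Two implementation points matter for correctness and reproducibility:

- **Gauge transport.** Eigenvector phases are parallel-transported along
  each trajectory (overlap with the previous step made real positive), and
  when a true or extremely narrow avoided crossing swaps the energy
  ordering, columns are relabeled by maximum overlap so indices follow the
  physically continuous states.  A pointwise phase convention alone
  produces sign discontinuities that decohere the estimator; the pointwise
  convention (largest component real positive) is still used at t = 0 and
  in the standalone eigensystem API so results are reproducible.
- **Seeding.** One master seed spawns a `SeedSequence` substream per member;
  hop uniforms are drawn per member up front, so any single trajectory can
  be replayed in isolation and ensembles are bit-reproducible.

Members whose |coeff| exceeds a cutoff (default 1e3) are frozen — no
further hops — and flagged; this is the usual variance-control measure for
short-time-propagation weights.  Transition sampling uses the real part of
P·d, exact for real Hamiltonians (all shipped benchmarks); complex-coupling
models propagate but their hop statistics are first-order only.

Cross-validation: on the spin–boson benchmark (gap 2, ω = 1, C = 0.2,
β = 1) a 10⁴-member ensemble at dt = 0.005 tracks the grid solution within
~2.3 standard errors at all output times to t = 5, and the deviation
shrinks with dt.  At substantially stronger coupling (C = 0.5) a
systematic residual of order 0.1 in ⟨σ_z⟩ survives dt refinement — the
known accuracy limit of momentum-jump short-time propagation — so the grid
solver remains the reference in that regime.

## Observables

Averages are Tr′∫ dX W O as grid quadrature or ensemble mean.  Correlation
functions ⟨O₁(t) O₂⟩ keep the literal operator order (O₂ attached at t = 0
by replacing the member's statistical factor with n² (O₂(X₀) w_S)_{b a});
they are complex in general, and a symmetrized (real-part) variant is
available on request.  Response spectra are windowed DFTs (Hann by
default) on uniform time grids with the dominant |ω| peak reported;
window and normalization ride along in the result.

## Bath discretization

An Ohmic spectral density J(ω) = (π/2) ξ ω e^{−ω/ω_c} is discretized by the
logarithmic rule ω_j = −ω_c ln(1 − (j−½)/N), c_j = ω_j √(2ξω_c/N): the
frequencies sample the normalized density and each mode carries an equal
share of the reorganization energy, so Σ c_j²/(2ω_j²) = ξω_c holds exactly
at every N (the continuum value, verified against quadrature).  The rule is
deterministic.

## Companion models

- Bohr frequency ω = ΔE/ħ and superposition lifetime τ = 2π/ΔE (ħ = 1),
  with the exact identity ω·τ = 2π property-tested over random gaps.
- Doubled-boson ("thermo-field") mode pair
  H = ω(a†a − v†v) + iγ(a†v† − av) on a truncated two-sector Fock space
  (dense diagonalization; spaces ≤ 40² states).  The interaction is a
  two-mode squeezing generator: from the vacuum,
  ⟨a†a⟩(t) = ⟨v†v⟩(t) = sinh²(γt), independent of ω, while the Casimir
  a†a − v†v is conserved exactly even after truncation.  Truncation leakage
  into the top Fock levels is monitored; above 1e-8 the computation refuses
  with a suggested larger cutoff.  Because a†a − v†v commutes with H, the
  vacuum only populates the paired states |n, n⟩; a Casimir-block solver
  evolves that tridiagonal subspace directly (dimension = cutoff), making
  strong squeezing (γt ≈ 2 needs a few hundred levels for 1e-6 accuracy)
  cheap.  Multi-mode sums are direct products of independent pairs.

## Configuration, outputs, provenance

Runs are configured in TOML (matrices as nested real/imag arrays);
validation aggregates all failures with their key paths.  Time series are
CSV, ensembles/grids HDF5, and every bundle carries a JSON sidecar with the
config hash, seed, code version, RNG-splitting rule, and invariant-check
results, plus a one-line-per-stage log — enough to regenerate any output
from the sidecar alone.  Reruns with the same config and seed are
byte-identical.

## Test problem sizes

The shipped test and acceptance workloads are desk-scale by design:
thermostat moments from 48 trajectories × 10³ time units (dt = 0.02),
conservation over 10⁵ steps (dt = 10⁻³), grids up to 128², trajectory
ensembles up to 10⁴ members × 10³ steps, Fock spaces up to 40² (dense) and
400 (Casimir block), and 10⁵-sample sampling checks.  These sizes put every
oracle comparison at tolerances far below the physical effects being
checked while keeping the full suite to minutes.

## What the synthetic scenarios do and do not emulate

The packaged scenarios (Rabi, zero-point mode, spin–boson) exercise the
solvers under the stated study conditions — few levels, one or few modes,
bilinear coupling, harmonic banks, thermal/zero-point Wigner initial
states.  They do not emulate anharmonicity, time-dependent driving,
spatially resolved fields, wave-function-collapse events, or macroscopic
mode banks; passing tests therefore validate the propagators, thermostats,
estimators and their contracts, not any claim about real neural or
condensed-matter systems.

## Known limitations

- The grid solver is a one-mode, small-n reference by construction.
- Trajectory hop statistics are first-order in dt with momentum-jump energy
  matching; strong coupling leaves a systematic residual (see above), and
  complex-valued couplings sample hops from Re(P·d) only.
- A single harmonic mode under one NHC chain is only marginally ergodic;
  the shipped defaults (chain length 2, M_η = T/ω², SY7 substeps) are
  validated for the kinetic moment and histogram tests, not for arbitrary
  observables at arbitrary stiffness.
- The doubled-boson model is the noninteracting single-pair building block;
  finite-temperature thermo-field machinery is out of scope.
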