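# Methods

## The model

`lvckit` works with linear vibronic coupling (LVC) Hamiltonians for a set
of N coupled diabatic electronic states |d_i⟩ over the F ground-state
normal modes of a molecule or molecular aggregate, in dimensionless
coordinates **q** with conjugate momenta **p**:

    H = T(p) + V(q)
    T(p)    = 1/2 p·Ω p                               (on every state)
    V_ii(q) = E_ii(0) + 1/2 q·Ω q + λ_ii·q
    V_ij(q) = E_ij(0) + λ_ij·q                        (i ≠ j)

Ω is the diagonal matrix of ground-state vibrational quanta (ħω_α, eV),
λ_ii are intrastate energy gradients, λ_ij interstate linear couplings,
and E(0) is the constant diabatic matrix at the reference (Franck–Condon,
FC) geometry. Constant off-diagonal couplings E_ij(0) appear whenever the
diabatic states are not the adiabatic states at the reference geometry —
the typical situation for fragment-localized diabatic states in a
hydrogen-bonded or stacked multichromophore such as a DNA base pair, where
one wants local excitations (bright ππ*, dark nπ*) and interfragment
charge-transfer (CT) states as the dynamical basis.

Closed forms used throughout: the diabatic minimum of state i lies at
q_α = −λ_ii,α/ω_α with energy E_ii(0) − Λ_i, where Λ_i = 1/2 Σ_α
λ_ii,α²/ω_α is the reorganization energy.

Units: energies and ħω in eV, dimensionless coordinates, time in fs with
ħ = 0.6582119569 eV·fs. Coupling vectors λ are in eV, consistent with the
constant matrix.

## Overlap-based diabatization

Given M ≥ N adiabatic states |a_m⟩ of the full system at some geometry and
N reference states |R_i⟩, the overlap matrix S_im = ⟨R_i|a_m⟩ defines the
diabatic states through Löwdin (symmetric) orthonormalization,

    D = (S Sᵀ)^(−1/2) S ,

the unique row-orthonormal matrix closest to S in Frobenius norm: the
diabatic states are the orthonormal combinations of adiabatic states that
resemble the references as closely as possible. The diabatic Hamiltonian
at that geometry is H^D = D diag(E^A) Dᵀ.

Three reference conventions are supported, differing only in what the
backend computed, not in the algebra:

* **St** — references are the adiabatic states of the full system at the
  FC geometry. At the FC point D is then the identity on the lowest N
  adiabatic states and E_ij(0) = 0 exactly (implemented as that special
  case rather than through a numerically-identity overlap).
* **FrD** — references are excited states of the isolated fragments (or
  interfragment orbital transitions, for CT states).
* **FrD_MMref** — fragment references computed in the electrostatic field
  (point charges) of the partner fragments.

Numerical choices: (SSᵀ)^(−1/2) via eigendecomposition with a hard
eigenvalue floor of 1e-10 — below the floor the transform refuses with an
error naming the reference state dominating the unspanned combination;
silent regularization would hide an inadequate adiabatic set. Diagnostics
per geometry: completeness (row norms of S, 1 = reference fully spanned)
and reference weights W_m = max_i S_im² (how diabatic each adiabatic state
is). Note the distinction exercised by the tests: with a complete
adiabatic set, completeness is exactly 1 even though weights stay below 1
whenever adiabatic states mix reference characters.

## Finite-difference parametrization

E(0) comes from diabatizing the FC record. Couplings come from central
differences over displaced geometries q = ±Δ_α e_α:

    λ_ij,α = [H^D_ij(+Δ_α) − H^D_ij(−Δ_α)] / (2Δ_α) .

On an exactly-LVC surface this is exact (the shared harmonic term cancels
between the two displaced points), which is what makes the synthetic
round trip an exact inverse. Default Δ_α = 0.1 (dimensionless),
configurable globally or per mode; a validity diagnostic reports the
second difference [H(+Δ)+H(−Δ)−2H(0)]/Δ², which must equal ω_α on the
diagonal and vanish off-diagonal, flagging anharmonic or quadratic-
coupling contamination (which biases λ as O(Δ²); the tests confirm the
Richardson ratio of 4 under step halving).

**Phase handling (a genuinely open design point).** Diabatic vectors D(q)
at different geometries are expressed in different adiabatic bases, so
row-wise sign alignment of raw D matrices across geometries is not
well-defined — adiabatic reordering between geometries makes the row
inner products meaningless, and acting on them corrupts the off-diagonal
finite differences. The pipeline instead projects each geometry's
diabatic states onto the geometry-independent reference basis (the rows
of D Sᵀ) and sign-aligns those against the FC point — always against FC,
never the previous geometry, so sign drift cannot accumulate. For a
healthy record set this is a no-op (Löwdin already makes D Sᵀ positive
semidefinite); it exists to catch backends with per-geometry reference
phase conventions, and it warns when an aligned inner product falls below
0.5 (likely state reordering). The generic row-sign utility
`phase_align(D, D_ref)` is exposed for same-basis comparisons.

Degenerate adiabatic pairs at displaced geometries (gap < 1e-6 eV) are
only warned about: the Löwdin transform stays well-defined as long as
S Sᵀ is nonsingular.

## Synthetic electronic-structure backend

The backend replaces the quantum-chemistry layer with an exactly known
ground truth so the whole pipeline is testable as a round trip: records
contain the lowest M eigenvalues of the truth potential at q and overlaps
of (optionally imperfect) reference states with the eigenvectors.
Controllable imperfections:

* truncation of the adiabatic set (M < N_truth) and/or fewer reference
  states than truth states — completeness drops below 1;
* a seeded orthogonal rotation of the references within each symmetry
  block, magnitude set by a mixing angle θ (references are then no longer
  eigen-combinations of the truth diabatic basis). The generator is a
  fixed random antisymmetric matrix of unit scale, so the perturbation —
  and hence the parametrization error — grows linearly and monotonically
  in θ; for a 2-state block the FC weights are exactly cos²θ, which the
  tests pin;
* per-state embedding shifts that re-derive the references from the
  shifted constant matrix, emulating the difference between isolated-
  fragment and MM-embedded fragment references (with zero shift this
  yields FC-adiabatic references, i.e. the St convention).

`make_truth_model` generates seeded models with the structure of a
photoexcited purine/pyrimidine pair at vertical excitation: bright ππ*
and dark nπ* local excitations on alternating fragments plus one CT
state; vertical energies in 5.0–6.8 eV; frequencies in 0.01–0.4 eV;
Cs symmetry with ~2/3 in-plane modes and couplings only in
symmetry-allowed slots; local-state reorganization energies drawn in
0.1–0.7 eV with the CT state pinned at 1.2 eV (charge separation
relaxes much more strongly than a local excitation, and the CT
reorganization is always the largest). What the generator does **not**
emulate: anharmonicity (the H-bond stretches that dominate
proton-transfer physics are genuinely anharmonic), root flipping or
SCF noise of a real TD-DFT backend, quadratic interstate couplings, and
conical-intersection topography beyond what LVC itself encodes. Green
tests therefore certify the diabatization/parametrization machinery, not
the LVC approximation for any real molecule.

## Wavepacket dynamics

The vibronic wavefunction is expanded on harmonic-oscillator product
bases of the ground-state surface (per-mode truncation n_max) times the
diabatic electronic states. All LVC matrix elements are analytic there —
q is tridiagonal, the harmonic-plus-kinetic part is the diagonal number
operator ω(n + 1/2) — so the projected Hamiltonian is sparse and the
propagation is exact on the truncated basis. For q² (needed for the PES
expectation observable) the exact pentadiagonal projection is used, which
keeps ⟨p² + q²⟩ consistent with the number operator at the basis edge.

Three interchangeable propagators: adaptive Lanczos with full
reorthogonalization (default; per-step Krylov convergence to 1e-12),
Chebyshev expansion with Bessel coefficients and Gershgorin spectral
bounds, and dense matrix exponential (small bases only). Tests hold all
three to ≤1e-9 of an independent eigendecomposition oracle, and the
acceptance script measures the deviation over 250 fs at n_max = 12
(observed ~1e-12); norm and total energy are conserved at the same level.
Output sampling defaults to dt = 0.25 fs — sampling density only, not an
integration step.

Observables: diabatic populations P_i = ⟨ψ_i|ψ_i⟩; diabatic-PES
expectations, by default conditional ⟨ψ_i|V_ii|ψ_i⟩/P_i and masked (not
NaN) where P_i < 1e-8, with the total (unnormalized) convention
available by flag and recorded in the output metadata — both are
physically defensible readings of a per-state potential-energy trace, so
neither is asserted as canonical; the autocorrelation ⟨ψ(0)|ψ(t)⟩; and
the total energy.

This is explicitly not a tensor-tree (ML-MCTDH) code: the contract is
"numerically exact on reduced models" (roughly ≤6 modes, ≤12 states;
the hard cap is on the total basis dimension). `reduce_modes` keeps the k
modes with the largest Σ_ij λ_ij,α², mirroring the resource-allocation
heuristic used in tensor-tree propagations, where strongly coupled modes
receive the largest bases. Full-dimensional (≈100-mode) dynamics are out
of reach of exact propagation by design and are not claimed.

## Absorption spectra

The contribution of bright state b is the damped half-Fourier transform
of its autocorrelation,

    I_b(E) ∝ f_b · Re ∫₀ᵀ C_b(t) g(t) e^{i(E+E₀)t/ħ} dt ,

with f_b the oscillator strength, E₀ the zero-point energy of the initial
vibrational state (so the axis reads as excitation energy from the
relaxed ground state), and g(t) = exp(−σ²t²/2ħ²) the time-domain
conjugate of an energy-domain Gaussian with σ = HWHM/√(2 ln 2); the
default HWHM is 0.04 eV. The total spectrum is the pointwise sum of
contributions, normalized to unit maximum of the total (each contribution
scaled by the same factor, preserving the sum rule). An optional photon-
energy prefactor (dipole-weighted vs oscillator-strength-weighted
conventions) is off by default and recorded in the metadata. A rigid
energy-axis shift is available purely as a plotting/comparison device.

The quadrature is a trapezoid rule over the sampled C(t); near a line at
E_n the integrand e^{i(E−E_n)t/ħ} is slowly varying, so fine time
sampling (0.02–0.05 fs in the tests) gives the analytic Gaussian to
≈1e-6. The time grid must be long enough that the damping suppresses
C(T) by ~5 decades, otherwise the truncated transform rings; shorter
grids are rejected with the required t_final in the message.

Analytic anchors used in tests: a stick transition broadens to a Gaussian
of exactly the requested HWHM; a single displaced oscillator (frequency
ω, gradient λ) yields a progression with Poisson intensities
e^(−S) Sⁿ/n! governed by the Huang–Rhys factor S = λ²/(2ω²).

## Problem sizes and defaults

Defaults chosen once as desk-scale study conditions: truth models of 12
states / 10 modes for round-trip validation (the spec-scale electronic
dimension with a reduced mode count), Δ = 0.1, propagation oracle on a
2-state/2-mode model with n_max = 12 over 250 fs sampled every 0.25 fs,
50 models for the minima cross-check, 200 matrices (N ≤ 12, M ≤ 40) for
the diabatization oracle. The test suite and the acceptance script rerun
all of these from scratch; neither reads any stored reference numbers.

## Known limitations

* Linear couplings only: no quadratic/anharmonic vibronic terms, no
  spin–orbit coupling, no finite-temperature initial conditions.
* The synthetic backend cannot emulate real electronic-structure failure
  modes (root flipping, SCF non-convergence) or reference states outside
  the truth diabatic space.
* Exact propagation scales exponentially with mode count; large systems
  must go through `reduce_modes` or the MCTDH operator export.
* The MCTDH operator writer targets the dialect accepted by MCTDH-family
  packages but is validated only against the bundled re-parser, not
  against an external installation.
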