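# Methods

## Physical model and assumptions

The package treats each emitter as a two-level system with a single narrow
optical dipole transition at frequency ω₀ (wavelength λ) and a real unit
dipole orientation. All emitters couple through the free-space
electromagnetic vacuum; after the Born–Markov elimination of the field the
pair couplings are the real and imaginary parts of the projected dyadic
Green's tensor (coherent part Ω_ij, dissipative part Γ_ij). The analysis is
restricted to the single-excitation manifold, appropriate for the
weak-field/linear-response conditions of light harvesting: there the
population-recycling term of the Lindblad dissipator only feeds the ground
state and the dynamics of coherences and excited-state populations is
governed by the non-Hermitian effective Hamiltonian
H_eff = diag(Δᵢ) + Ω − iΓ/2. Phonons, multi-excitation effects, external
drive and any medium or surface corrections to the Green's tensor are
outside the model.

Dipole orientations on a ring are parameterized in the local frame by the
polar angle θ (from the vertical) and azimuth φ:
p̂ = sinθ cosφ ê_φ + sinθ sinφ ê_r + cosθ ê_z. This single convention (cosθ
multiplying ê_z) is used everywhere; in it the Dicke-limit bright-mode
rates read Γ_{m=0} = NΓ₀cos²θ and Γ_{m=±1} = (NΓ₀/2)sin²θ.

## Units

Lengths in λ (so k₀ = 2π), rates and frequency shifts in the single-emitter
decay rate Γ₀, ħ = 1. The dipole moment strength and ε₀ are absorbed into
the Γ₀ = 1 normalization; scattered-field prefactors are set to one, so
intensities are in arbitrary units (every comparison the package makes of
field patterns is ordinal, never absolute).

## Symmetry reduction

An N-fold symmetric structure (each of the stacked rings shares the same N)
is organised into N unit cells of n_cell components. H_eff is then block
circulant: the coupling between cells depends only on their separation ℓ.
The code verifies this property explicitly before reducing (tolerance 1e−9
relative to the largest coupling magnitude — couplings reach 10⁶–10⁷ Γ₀ at
light-harvesting separations, where an absolute tolerance would flag pure
floating-point roundoff) and raises with the worst offending pair if the
input violates it. The canonical angular-momentum set is the N integers in
(−N/2, N/2]; for odd N this is the symmetric set 0, ±1, …, ±(N−1)/2, and
for even N it includes the unpaired band-edge value m = N/2 once. The union
of the Bloch-block eigenvalues reproduces the dense spectrum to machine
precision (tested).

Eigenvectors are right eigenvectors normalized under the standard inner
product; component "populations" are their squared magnitudes, which sum to
one and match the usual ring-occupation-probability reading. Degenerate ±m
pairs are reported separately; tests compare eigenvalue multisets, never
eigenvectors, across degeneracies.

## Numerical choices

- **Small-separation cancellation.** The dissipative scalars entering Γ_ij
  are O(x³) differences of O(x) sin/cos terms at x = k₀r ≪ 1 — precisely
  the light-harvesting regime (x ~ 10⁻²). Below x = 10⁻² the code evaluates
  them from 12-term Taylor series; the direct and series paths agree to
  ~10⁻⁷ relative across the switchover window (the direct path's own
  double-precision bound is ~3·eps/x²), and the production curve is
  continuous at the threshold (tested). The coherent scalars are dominated
  by the 1/x³ near-field term and need no special handling.
- **Spectral tolerances.** Eigenvalue comparisons use 1e−9 scaled by the
  spectral magnitude: for the LH2-type fixtures with 10⁷ Γ₀ detunings a
  double-precision eigensolver carries ‖H‖·eps ≈ 10⁻⁸ absolute error, so an
  unscaled 1e−9 would test the eigensolver, not the physics.
- **Deep-subradiant rates.** Rates below ‖H‖·eps (e.g. 10⁻¹²–10⁻¹³ Γ₀ for
  nearly-coincident rings with near-field couplings of 10⁴ Γ₀) are at the
  numerical noise floor; conclusions about such modes are drawn from the
  location and shape of rate curves, never from their absolute values.
  Tiny negative computed rates of this magnitude are roundoff, not physics;
  the Γ matrix itself is verified positive semidefinite.
- **Branch tracking.** Rotation sweeps track the two Bloch branches by
  maximal eigenvector overlap between adjacent grid points, so a branch
  follows its physical character through an avoided crossing (the tracked
  branches exchange energetic order exactly once there). Exact degeneracies
  are flagged, not fatal.
- **Avoided-crossing location.** δ_c is the argmin of the gap between the
  two branch frequencies on a 400-point grid, refined by a three-point
  quadratic fit; a monotone gap reports "no crossing" rather than a
  boundary value.
- **Broad subradiance minimum.** For two identical rings the aligned
  configurations δ = 0 and δ = 2π/N host a trivially dark antisymmetric
  mode, and exactly at an avoided crossing the darkest rate can graze zero
  over a ~10⁻³ rad window. The physically meaningful optimum of the
  rotation — the one robust to small angular disorder — is the *broad*
  interior minimum, located as the interior local minimum of the log-rate
  curve smoothed over 5% of the swept range, with 10% of the range trimmed
  at each end to exclude the aligned limits. For the reference rotated
  double ring this sits at the interleaved configuration δ = π/N with
  inter-ring phase |η| ≈ π/2, stably across grid resolutions.
- **Ties.** "Most subradiant mode" breaks rate ties by smaller |m|, then
  lower branch index, for deterministic reporting.

## Closed-form limits and their quality

- **Dicke limit.** For rings much smaller than λ the exact bright-mode
  rates converge to the effective-dipole forms above; at N = 20, R = 0.05λ
  the m = 0 transverse rate is 19.22 Γ₀ (within 4% of NΓ₀ = 20) and the
  in-plane m = ±1 rates are within 5% of NΓ₀/2. Note that a ring with the
  *lattice constant* d = 0.05λ (radius 0.16λ) is already outside this
  regime: its m = 0 rate is 13.1 Γ₀ and its m = ±1 modes exceed Γ₀. The
  small-ring reference geometry is therefore specified by radius
  R = 0.05λ.
- **Cosine band.** The nearest-neighbour approximation
  Ω_m ≈ 2Ω_d cos(2πm/N), with Ω_d computed exactly from the Green's tensor,
  captures the band edges of the N = 20, R = 0.05λ tangential ring to ~20%
  (measured: 17% at m = 0, 11% at m = N/2); longer-range couplings shift
  the m = 0 edge hardest, and mid-band values where the cosine vanishes are
  not meaningful.
- **Light line.** m₀ = N·d/λ separates radiant (m ≲ m₀) from guided
  (m ≳ m₀) modes on a large dense ring; the brightest radially-polarized
  mode of the N = 100, d = λ/3 ring sits at |m| = 30, just below
  m₀ = 33.3. Guided exponential suppression with N exists only for
  d < λ/2 (tested by doubling N at fixed d on both sides of the
  threshold).
- **Subradiance scaling.** At fixed d the darkest double-ring mode is
  darker than the single ring's at every N and its exponential suppression
  with N is steeper. The min-rate curve alternates between even N (where
  the unpaired band-edge mode m = N/2 exists and is darker) and odd N — a
  physical parity effect — so log-linear fits are performed within one
  parity class (even N), where R² > 0.99.

## The LH2 fixture is synthetic

The three-ring LH2-like geometry shipped as `lh2_fixture` /
`lh2_default_params()` is an explicitly approximate, synthetic parameter
set patterned on the published structural scale of the complex (B850 ring
radius ~2.6 nm, B800 radius ~3.1 nm, plane separation ~1.7 nm, transition
wavelength ~850 nm, B800–B850 detuning of order 10⁷ Γ₀, dipoles mostly
in-plane with small alternating vertical tilts). It is *not* a
crystallographic data set, and no numerical output computed from it should
be compared against measured LH2 values. What the fixture does reproduce —
and what the tests assert — is the qualitative structure: a strongly
hybridized B850 pair forming a bright low band (exactly two bright modes,
at m = ±1, the quasi-symmetric combinations) and a dark high band below
the B800 band; one-hot populations when the inter-component couplings are
zeroed; and, under uniform size scaling R → αR, a population crossing of
the third band at α_c < 1 that recedes from 1 with growing m (measured
α_c = 0.84, 0.78, 0.69, 0.52 for m = 1–4).

## Problem sizes

All shipped analyses are desk scale: dense systems of ≤ 200 emitters,
Bloch blocks of ≤ 3×3, sweep grids of ≤ 625 points (landscape) / 400
points (rotation). The full test suite runs in a few seconds; each
acceptance-style analysis in well under a minute.

## Known limitations

- Real dipole orientations only; complex (circular) polarization is
  rejected.
- No disorder: positions and detunings are exact; the symmetry check will
  (correctly) refuse disordered input for the Bloch path, and the dense
  path should be used instead.
- Decay rates below the ‖H‖·eps noise floor are location-reliable but not
  value-reliable (see above); quadruple precision would be required for
  their absolute values.
- The scattered field is the emitted field of a prepared mode; no input
  drive, saturation, or detection model.
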