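# Methods

This note documents the model implemented by `chlorosim`, the choices made
where the design was genuinely open, and what the synthetic world does and
does not establish.

## Model overview

The package simulates the Q_y exciton band of a single chlorosome-type
cylinder with the time-dependent Frenkel Hamiltonian

H(t) = Σₙ (ω₀ + Δωₙ(t)) Bₙ†Bₙ + Σ_{m≠n} J_mn Bₘ†Bₙ,

ω₀ = 15390 cm⁻¹ (monomeric BChl *c* Q_y gap), Bₙ hard-core-boson
operators.  Couplings use the point-dipole approximation with the vacuum
prefactor 5034.12 cm⁻¹·Å³·D⁻² and μ = 5.48 D; no screening is applied and
no distance cutoff is used by default (distant weakly-coupled pairs are
retained; an optional cutoff exists purely for speed).  Phase accumulation
uses 2πc = 1.88365×10⁻⁴ rad/(cm⁻¹·fs).

The quantum-classical propagation is one-way (the bath drives the exciton
system; no feedback) and sits in the high-temperature limit: there is no
detailed-balance correction, so at long waiting times populations tend
toward equal weighting of all states.  On the sub-picosecond timescales the
package targets this is the standard, well-tested regime of the
numerically-exact-per-frame ("NISE") family of methods; quantitative
thermalisation at long t₂ is *out of scope*.

## Synthetic geometry

The cylinder wall is a two-site-basis (syn/anti) lattice rolled onto a
cylinder: `n_per_ring` stacks, displaced purely circumferentially, each
winding at the chiral angle δ = 112.3° measured from the long axis
(δ = 0 would put stacks parallel to the axis).  Each site carries a unit
dipole expressed in its local (stack tangent, in-surface normal, radial)
frame via a polar tilt and per-sublattice azimuths.  The radius follows
from the closure condition 2πR·|cos δ| = n_per_ring · interstack_spacing,
so every Mg position lies exactly on the cylinder surface.

The literature model this emulates never published its lattice constants.
They are fixed here by `calibrate_geometry`: a seeded brute-force grid plus
random search (with Nelder–Mead polish) over five free constants (stack
spacing, inter-stack spacing, dipole tilt, two azimuths) against the three
printed observables — mean dipole-axis angle β = 54° (±2°),
nearest-neighbour coupling −450 cm⁻¹, inter-stack couplings +200/−200 cm⁻¹
(±10 %).  Two solution branches reproduce those scalars.  The branch with
near-*antiparallel* consecutive stack dipoles yields an H-aggregate-like
band (blue-shifted, superradiance near the band top), contrary to the
well-established J-aggregate phenomenology of chlorosomes; the calibration
search space is therefore restricted to the near-parallel branch, which
gives the expected ~600 cm⁻¹ red shift and superradiant states in the
lower part of the band.  The winning constants are frozen as the
`GeometryParams` defaults (a ≈ 6.61 Å, b ≈ 7.85 Å, tilt ≈ 43.4°,
azimuths ≈ 28.6°/90.7°; R ≈ 65.8 Å at 20 stacks), so default builds need
no search.

Because the lattice is deterministic and helically symmetric, each
structural pair class has a single coupling value; histogram peaks are
therefore sharp.  Nearest-neighbour steps alternate syn→anti/anti→syn with
slightly different couplings (−450 / −423 cm⁻¹); the histogram peak finder
merges them into one peak centred near −437 cm⁻¹, within the ±10 %
structural tolerance.

## Site-energy disorder

The published fluctuations come from MD + quantum chemistry and are not
public.  The surrogate is, per site, a static Gaussian offset
(σ_static = 300 cm⁻¹) plus an Ornstein–Uhlenbeck process
(σ_dynamic = 400 cm⁻¹, τ_corr = 50 fs) sampled with the exact discrete
transition at dt = 4 fs, independent across sites.  The magnitudes are
order-of-magnitude choices producing a broad, partly inhomogeneous band
(instantaneous site σ ≈ 500 cm⁻¹, i.e. comparable to |J_nn|); they are
config-exposed, not fitted.  Streams are split per (realization, site) from
one master seed, so adding sites or realizations never reshuffles earlier
draws.

**What the surrogate does not capture:** spatial correlation of the
electrostatic environment between neighbouring pigments, non-Gaussian
tails, coupling fluctuations from nuclear motion (couplings are static
here — the lattice does not move), and intramolecular vibrations (also
neglected in the emulated model).  One measurable consequence: with
independent Gaussian disorder of this strength the N ≈ 500 band edge
contains Lifshitz-tail states localised on single outlier sites, so the
requirement "all ten lowest states have PR ≥ 2 in every frame" holds in
only ~30 % of realizations (median frame-minimum PR ≈ 1.8).  The
corresponding acceptance test is deliberately left failing rather than
tuning σ or the seed; see the ledger note in the repository history /
test docstring.

## Propagation

Each 4 fs frame's propagator is built by eigendecomposition,
U = V·exp(−i·2πc·E·Δt)·Vᵀ, hence exactly unitary; long-time propagation is
the ordered product (norm drift < 10⁻⁹ over 500 fs is tested).  The
two-exciton manifold (pair dimension P = N(N−1)/2, lexicographic (m<n)
indexing — ESA bookkeeping depends on this order) is propagated either

* **exactly** (dense eigendecomposition per frame) for P ≤ 700, or
* **matrix-free** by a Chebyshev expansion of exp(−iH₂Δt) whose
  matrix-vector product uses the identity that H₂ acting on a symmetric
  zero-diagonal coefficient matrix C equals offdiag(H₁C + CH₁) — O(N³)
  instead of O(P²) per product.  Spectral bounds come from Gershgorin
  discs; coefficients are Bessel functions truncated at 10⁻¹³, giving
  agreement with the exact route to ~10⁻¹³ (tested).

## Spectroscopy

Impulsive-limit third-order response with interaction times τ₀=0, τ₁=t₁,
τ₂=t₁+t₂, τ₃=t₁+t₂+t₃:

* GSB: [μ·U(τ₃,τ₂)·μ] · conj[μ·U(τ₁,τ₀)·μ] (ground state during t₂ —
  exactly t₂-invariant for a frozen Hamiltonian);
* SE: [μ·U(τ₃,τ₁)·μ] · conj[μ·U(τ₂,τ₀)·μ];
* ESA: −⟨μ⁽¹²⁾b(τ₃) | W(τ₃,τ₂) μ⁽¹²⁾k(τ₂)⟩ with one-exciton bra/ket paths
  and the pair-promotion map ⟨mn|μ⁽¹²⁾|n⟩ = μ_m; the minus sign makes
  induced absorption negative while GSB/SE are positive (bleach red,
  absorption blue in the maps).

Rephasing conjugates the first interaction, nonrephasing the second.  Each
interaction carries a Cartesian index; the all-parallel isotropic average
is the analytic fourth-rank contraction
⟨xxxx⟩ = (1/15)Σ_ab [A_aabb + A_abab + A_abba]
(Monte-Carlo rotational sampling is kept as a test oracle only).
Implementation notes:

* cumulative propagators G_t = U(origin+t, origin) turn every one-exciton
  amplitude into a dot product of precomputed tables (G is cached per
  realization, N ≤ ~120 recommended for 2DES);
* ESA propagates pair wavefunctions **only during t₃**, marching over
  absolute frames so all active t₁ slots share each frame's two-exciton
  step (batched through the Chebyshev route at large N);
* all coherences are demodulated against a rotating-frame reference
  (default ω₀) before transforming — the bare carrier is undersampled at
  4 fs — and the frequency axes are shifted back;
* apodization is exp(−t/(2τ)) per coherence axis with τ = 300 fs, i.e. a
  Lorentzian lineshape of *lifetime* τ (the factor 2 is stated because
  "lifetime" is ambiguous); t = 0 edges are half-weighted; zero padding
  defaults to ×4 (peak positions quoted to ~10 cm⁻¹ depend on it);
* the absorptive spectrum is Re(rephasing + nonrephasing) with the t₁
  kernels chosen so both phases land at positive ω₁;
* realization origins are spaced `realization_stride` frames (default 250
  = 1 ps) along one long disorder trajectory, ten realizations by default;
* the t₂ grid is exactly 24 fs (multiples of the 4 fs frame step);
  point traces use nearest-gridpoint lookup.

Amplitudes are in arbitrary units; the published normalisation (to the
t₂ = 0 total-spectrum maximum) is available to callers as a trivial
post-scale.

## Band analysis

Participation ratio uses the number-of-sites convention
PR = (Σ|c|²)²/Σ|c|⁴ (1 = localised, N = uniform); the alternative 1/N-
valued convention would make the documented "PR ≥ 2" dark-state flag
meaningless.  Oscillator strength is f_k = |Σₙ c_kn μₙ|² with the exact
sum rule Σ_k f_k = Nμ².  The coupling histogram uses 20 cm⁻¹ bins, treats
|J| < 50 cm⁻¹ as the central distant-pair region, and accepts local maxima
with ≥ 5 % prominence relative to the tallest non-central bin; peak centres
are count-weighted means over the monotonically descending flanks, and
peaks are assigned to structural classes (same-stack nearest neighbour vs
adjacent-stack) by majority vote of their member pairs.  The dark-state
report caps f-ratios at 10⁶ to stay finite for exactly dark states and
flags states with PR ≥ 2 and f-ratio ≥ 10 as "dark-type
multichromophoric".  Multi-frame band reports pool DOS/PR/f over frames
(the ensemble-averaging mode); the dark-state table is per-frame.

## Defaults at a glance

| parameter | value | note |
|---|---|---|
| ω₀ | 15390 cm⁻¹ | monomer Q_y gap |
| μ | 5.48 D | per-site transition dipole |
| δ | 112.3° | chiral angle (from long axis) |
| Δt | 4 fs | frame step; nuclear motion frozen within |
| σ_static, σ_dynamic, τ_corr | 300, 400 cm⁻¹, 50 fs | stochastic surrogate |
| t₁, t₃ grid | [0, 196] fs, 4 fs | coherence times |
| t₂ grid | [0, 480] fs, 24 fs | waiting times |
| τ_apod | 300 fs | Lorentzian apodization lifetime |
| realizations | 10 × 1 ps stride | response averaging |
| zero padding | ×4 | frequency-domain interpolation |

## Known limitations

* Desk scale only: the full 2675-pigment 2DES computation of the emulated
  study is far outside a single-CPU budget; the test suite runs N = 60 for
  2DES and N = 500–1000 for structural/band analysis.  Finite-size effects
  (e.g. resolvable perpendicular-polarised subpeaks) are expected at these
  sizes.
* Static couplings, independent site noise, no intramolecular vibrations,
  no detailed balance, single wall (multi-wall systems can be composed
  from unions of geometries but are untested), all-parallel polarisation
  only, no finite pulse effects.
* A green test suite establishes internal correctness against exact
  oracles and the printed structural benchmarks — not agreement with
  experimental chlorosome spectra.
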