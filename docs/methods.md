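# Methods

This note documents the models behind each pipeline stage, the parameters
that matter, the numerical choices, and what the desk-scale fixtures do and
do not demonstrate about real experiments.

## SASE pulse model

A SASE shot is modelled as a train of `n_spikes` Gaussian intensity spikes
whose widths are the coherence time (default 0.25 fs, jittered ±30%) and
whose amplitudes are exponentially distributed, as expected for the
intensity of a chaotic source.  Spike centres are drawn from a Gaussian
whose variance is `sigma_env^2 − sigma_spike^2`, so that the seed-ensemble
mean profile — centre distribution convolved with the spike kernel — is a
Gaussian with *exactly* the requested FDHM.  (Multiplying a fixed envelope
into the spike train, the more obvious construction, shrinks the ensemble
FDHM by ~√2 and fails the stated 10% ensemble tolerance.)  With
`n_spikes=1` the generator returns the smooth envelope itself, a convenient
degenerate case for tests.  Per-shot totals are
`mean_photons × (1 + N(0, jitter_rel))`, clipped at zero.

Defaults: FDHM 9 fs, 13×10¹¹ photons, jitter 0.25/13, 5 keV photons,
36 spikes, dt = 0.1 fs.  The time grid spans ±2.55 × FDHM, the ratio of the
full simulated durations to the FDHM in the study conditions this package
emulates.  The beamline is a scalar transmission factor (default 2.3 — the
pulse energy loss from mirror aperturing) and a Gaussian focus (default
250 × 160 nm² FWHM); peak fluence is N/(2π σₓσᵧ) with σ = FWHM/(2√(2 ln 2)).
The temporal structure is inherited unchanged, by construction.

## Radiation-damage engine

Electronic damage is a per-atom Monte-Carlo process over fluence slices
(default 100 per pulse; snapshots at slice midpoints, weighted by the
fluence fraction delivered in the slice).  Photoionisation events per atom
and slice are Poisson with mean σ(Z, n_bound) × F_slice, where the neutral
cross section at the photon energy comes from the Cromer–Liberman imaginary
anomalous term (σ = 2 rₑ λ f″, via gemmi) and the charge-state dependence is
the uniform-depletion model σ ∝ n_bound/Z.  Ejection prefers the K shell
when the photon energy exceeds the K edge (for Fe at 5 keV it does not, so
Fe ionises from the L shell); a K hole schedules an Auger ejection after an
exponential lifetime (embedded per-element K-hole lifetimes: C 10.6 fs,
N 7.2, O 4.4, S 1.1, Fe 0.53), which ejects a second electron and refills
the hole.  Photoelectrons carry E_photon − E_binding and are spawned
isotropically.

Ions and free electrons move under softened Coulomb forces
(k q₁q₂ r / (r² + s²)^{3/2}, s = 0.1 Å) integrated by velocity-Verlet at a
10 as step.  Electrons farther than 1.5 × the sample radius (min 5 Å) from
the centre with positive total energy are removed and counted as escaped —
the energetic photoelectrons that carry most of the absorbed energy out of
a finite sample.  Slower secondary cascades, fluorescence and plasma
screening are not modelled.  With zero fluence nothing is charged and the
integrator is skipped, so the zero-fluence trajectory is bit-exactly
static.

The engine is meant for desk-scale molecules (tens of atoms; forces are
O(N²)).  For full-size molecules the frozen-atom closed form
`estimate_photoionisations` (Σ σⱼ × peak fluence) provides the event-count
diagnostic; it overestimates a dynamic simulation because ionised atoms
absorb less.  The dose diagnostic is n_events × E_photon / molecular mass,
with the mass including hydrogens even though hydrogens are excluded from
the scattering atom list.  (Note the 1000 Da / 1000 eV hand example some
derivations quote as ~96.5 GGy treats the mass in grams; in SI the value is
0.0965 GGy, and the 64 kDa / 3,500-event case gives 26.4 GGy either way it
is rounded in the literature to 25.)

## Diffraction forward model

Pixels map to scattering vectors q = (2π/λ)(k̂_out − k̂_in) on the Ewald
sphere; solid angle A cos³θ/L², horizontal-linear polarization
1 − (k̂_out·x̂)².  The coherent amplitude is the occupancy-scaled atomic
sum F(q) = Σⱼ (nⱼ/Zⱼ) fⱼ(|q|) e^{iq·Rrⱼ} with IT92 form factors — the
uniform-depletion approximation to per-configuration form factors.  The
incoherent term is Σⱼ (nⱼ/Zⱼ) Sⱼ(|q|) + n_free with the closure
approximation S(q) = Z(1 − (f(q)/f(0))²) (exactly 0 at q = 0, → Z at large
q) and a flat Thomson-like unit term per free electron; no Compton profile
broadening or photon-energy shift (no detector energy response is in
scope).  A pattern expectation is the fluence-weighted sum of per-snapshot
coherent (+ optional incoherent) intensities, zeroed on masked pixels, and
photon counts are independent Poisson draws per pixel, deterministic per
seed.

Detector defaults: 81×81 pixels of 300 μm with a 7-row central gap; the
sample–detector distance is chosen so the diagonal corner reaches 3 Å
full-period resolution at the photon energy.  The desk-scale fixture
detector is the 41×41 version of the same geometry.  At 5 keV this corner
sits at 2θ ≈ 49°, so the Ewald sphere is strongly curved — which is what
breaks the in-plane Friedel twin ambiguity in orientation recovery.  A side
effect of the short distance is that the 7-row gap is angularly wide: the
smallest unmasked |q| is ≈ 0.55 Å⁻¹, and the EMC volume is simply
unmeasured inside that radius (tracked explicitly, see below).

## EMC orientation recovery

The model for pattern counts at rotation r is W_rk = c_k · V(R_rᵀ q_k),
where V is the 3D intensity volume (default 33³ voxels, q = 0 at the
central voxel, dq chosen so the rotated detector fits the grid) sampled by
trilinear interpolation, and c_k is the known per-pixel solid-angle ×
polarization factor normalised to mean 1.  c_k is pixel-dependent but
rotation-independent, so it cannot be absorbed into V; omitting it
misspecifies the Poisson model badly enough to break orientation recovery.

The E-step computes log-domain posteriors P_dr ∝ w_r exp Σ_k [K_dk log W_rk
− W_rk] over unmasked pixels.  The M-step and compression are merged: with
A_rk = Σ_d P_dr K_dk and B_r = Σ_d P_dr, the EM Q-function
Q(V) = Σ_rk [A_rk log(c_k (TV)_rk) − B_r c_k (TV)_rk] is increased by
Richardson–Lucy multiplicative updates V ← V · (Tᵀ(A/TV)) / (Tᵀ(B·c)),
iterated a few times (default 8) from the *previous* volume, with T the
sparse trilinear-expansion operator.  Because each inner update cannot
decrease Q, the data log-likelihood trace is non-decreasing by the standard
EM argument — the classic scatter/normalise compression heuristic does not
give that guarantee.  Friedel symmetrisation (on by default, justified by
real scattering densities) is folded into the linear operator by
symmetrising numerator and denominator, which preserves the guarantee.

Voxels that accumulate less than ~2 pixel-samples of interpolation weight
(or, for degenerate few-rotation quadratures, a tenth of the median
coverage) are fixed at zero and flagged unmeasured: maximum likelihood at
such voxels reproduces single stray photons and produces huge spurious
spikes at the sparsely sampled rim of the volume.  The unmeasured mask
(central gap region, rim, low-coverage voxels) is carried on the volume and
honoured by phasing.

The SO(3) quadrature is the deterministic super-Fibonacci spiral with
uniform prior weights (a seeded Haar-uniform alternative exists).  The
desk-scale default is 600 rotations (~26° nearest-neighbour spacing): a
150-rotation quadrature (~38°) was found to be too coarse — tomograms ~19°
from a pattern's true orientation fit no better than Friedel-twin nodes
even when scoring against the ground-truth volume, and the most-likely
assignment degenerates.  Initialisation is uniform random positive (seeded)
scaled to the mean counts per pixel.  Because EM can lock into a poor
local optimum from an unlucky start — and the data log-likelihood itself
identifies such runs, typically ~1% below the good basins — a de-novo run
burns in several independent initialisations (default 8, for 12 iterations
each) and continues the one with the highest likelihood; the concatenated
trace remains non-decreasing.  Most-likely ties break to the lowest
rotation index; iteration stops at `n_iter` (default 50) or when the mean
relative volume change drops below `tol` (default 1e-4).

Recovered orientations are defined only up to one global rotation.
`orientation_errors` removes that gauge by trying right-gauge candidates
g = t̄ᵢ·aᵢ from a subsample of patterns and keeping the one minimising the
median geodesic error.  Note that independent EMC runs also quantise
orientations to *different* node sets, so two reconstructions of the same
data agree only up to quadrature-quantisation noise; the seed-agreement
property is therefore tested on a high-count, many-pattern fixture where
that noise averages down, and compared over mutually measured voxels.

## Difference-Map phasing and shrinkwrap

Phasing works on the centred intensity grid with √I as the Fourier-modulus
target; unmeasured voxels (gap, rim) are unconstrained.  The projectors are
P_S (real part, clipped non-negative inside the support, zero outside) and
P_M (replace moduli by √I at measured voxels); both are idempotent.  The
update is the standard two-estimate Difference Map
x ← x + β[P_S((1+1/β)P_M(x) − x/β) − P_M((1−1/β)P_S(x) + x/β)], β = 0.85 by
default, 300 iterations per run, from a seeded random-phase start; the
output density is P_S of the final iterate and the error trace is the
relative Fourier-modulus error of P_S(x).

The initial support is the thresholded autocorrelation (|IFFT(I)| >
threshold_frac × max, default 0.1, largest connected component).  A
shrinkwrap round runs an ensemble of random starts (desk default 16; the
production-scale 500 remains available in configuration), ranks them by
final modulus error, keeps the best `select_frac` (default 0.2 — the
selection rule is a package choice, standard practice where the ranking
criterion is not otherwise pinned down), aligns them by inversion + integer
translation via FFT cross-correlation, averages, thresholds at
`threshold_frac` × max, blurs with a uniform 5×5×5 kernel and re-thresholds.
The re-threshold is at half of one kernel vote (0.5/125) rather than
literally > 0, which would admit float-rounding dust far outside the true
dilation.  The new support never grows beyond the blurred previous support
and keeps its largest connected component.  `phase_pipeline` alternates
ensembles and support updates, then averages the selected final ensemble
and reports the PRTF and the half-PRTF resolution.

## Figures of merit

σ(**q**) is the per-voxel population standard deviation over aligned
reconstructions divided by their mean (population convention, matching the
moment notation ⟨…⟩ₙ; the sample convention is an option), shell-averaged
in one-voxel-wide |q| shells with the per-shell standard deviation as the
error bar; zero-mean voxels are excluded and counted.  The PRTF is the
shell-averaged modulus of the mean unit phasor over reconstructions, and
the resolution is 2π/q* at the first linear-interpolated 0.5 crossing
(a curve that never crosses reports the grid-edge resolution with a
"not limited" flag).  Volume alignment searches the rotation quadrature,
its inverses and the identity, always tests the inversion branch, scores
real-space correlation on the inscribed ball (rotations resample it without
clipping corners), and polishes the best candidate with a local
derivative-free (Powell) refinement — a hard 10° refinement radius proved
too restrictive in practice and the refinement is instead accepted whenever
it improves the correlation.

## Fixtures and what the tests show

The fixtures are deterministic per seed: `point`, `pair` (two carbons 10 Å
apart), `tetrahedron` (edge 5 Å), `random-cluster` (default 20 atoms,
C:N:O:S = 32:9:10:1, uniform in an 8 Å-radius ball — a looser packing than
real protein, chosen so the toy has several speckles across the detector),
and `protein-64kda`, a synthetic 4,735-atom, 64 kDa stand-in with a
4Fe/24S metal content used for frozen-atom event-count and dose
bookkeeping.  Known-orientation pattern sets draw quasi-uniform
orientations (globally re-oriented per seed), scale the undamaged
single-snapshot expectation so the mean total equals the photon budget
(default 200 photons/pattern — the photon-sparse regime of interest), and
Poisson-sample with per-pattern child seeds.

Desk-scale problem sizes — 20 atoms, 41×41 pixels, 2,000 patterns, 33³
voxels, 600 rotations, 16-member phasing ensembles — are the package's
standing choices for a pipeline that completes in minutes on one CPU; the
corresponding production-scale values (4,735 atoms, 200,000 patterns, 77³
voxels, 500 reconstructions) remain expressible in configuration.  Passing
desk-scale tests demonstrates the statistical machinery (Poisson
likelihoods, EM monotonicity, projector algebra, metric conventions) and
qualitative physics (damage-induced speckle-contrast loss, isotropic
Compton background degrading phasing, longer pulses displacing atoms
further), not quantitative fidelity to any full-scale experiment: the toy
molecule has no secondary structure, the detector is angularly extreme, the
damage engine's atomic data are reduced to one cross section per element
and charge state, and hydrogen scattering is ignored.

## Reproducibility

A single master seed expands into per-stage, per-item child seeds through
`numpy.random.SeedSequence` (`spisim.io.child_seed`), recorded in outputs,
so any individual pulse, trajectory, pattern or reconstruction can be
regenerated in isolation.  All HDF5 artifacts carry a schema-version
attribute checked on read; volumes with non-finite values are refused at
write time.
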