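# Methods

## Scope and model

The package reproduces, on synthetic data, the quantitative analyses that
underpin structural claims about a multi-ring rotary motor: cyclic-symmetry
determination from density maps, concentric-ring stoichiometry from
circumference ratios, symmetry-mismatch registration, radial feature
measurement on azimuthally averaged maps, map–model FSC scoring, and dwell
counting from tethered-bead rotation traces. Everything operates on two
kinds of objects: cubic-voxel density volumes (symmetry axis = the z line
through the box centre, θ counter-clockwise from +x viewed from +z) and
uniformly sampled x,y bead trajectories.

## Synthetic density phantoms

A phantom is a sum of components on a common axis:

- **Protomer rings** — n copies of a Gaussian-blob protomer placed at
  equal azimuthal spacing on a circle (radius r, height z, phase φ). The
  default protomer is an asymmetric three-blob "L" (σ = 2.5–3 Å, offsets up
  to 6 Å) so that azimuthal phase and handedness are detectable; a
  two-blob vertical "post" emulates C-ring protomer architecture.
- **Concentric disks** — rings built from a first ring of n₁ protomers at
  r₁ via the arc-width model: w = 2π·r₁/n₁, ring k at r₁+(k−1)Δr with
  round(2π·r_k/w) protomers (round half away from zero; near-half counts
  are flagged, keeping rounding-model ties visible).
- **Featureless tubes** — analytic lathed annuli (Gaussian wall profile,
  boxcar-with-Gaussian-rolloff axial profile), e.g. the rod and the
  β-collar fixtures.

Additive Gaussian noise is parameterized by a whole-map SNR: noise sd =
clean-map RMS / SNR (the usual variance-ratio convention). The optional
missing wedge zeroes Fourier coefficients with |k_x| < |k_z|·tan θ_w
(tilt axis y, beam axis z; default half-angle 33°, i.e. a ±57° tilt
range); the strict inequality keeps the always-sampled k_z = 0 plane.
Every generator is a pure function of its spec including the seed.

**Standard phantom geometry** (192³ voxels at 2 Å; 2 Å matches typical
pixel scales of the real maps, and the box is desk-scale): C17 scaffold
ring at r = 120 Å, z = +30 Å; C38 post ring at r = 150 Å, z = −80 Å; C26
ring at r = 80 Å, z = +70 Å; featureless rod of radius 25 Å. Radii and
heights are compressed relative to a real motor so the whole
symmetry-mismatched stack fits one desk-scale box — only the cyclic orders
and the separability of the analysis annuli matter to the analyses, not
absolute dimensions. The three annuli (r and z windows ±20 Å around each
component) are bundled with the phantom.

## Cylindrical analysis

`resample_cylindrical` samples the volume trilinearly on an (r, θ, z) grid
(r and z at voxel pitch, θ a power of two ≥ 256 samples so azimuthal FFTs
are exact over the period); points outside the box are NaN (absent), never
zero-filled. The azimuthal power spectrum over an annulus is
P(m) = Σ_{r,z} r·|F_m(r,z)|² (area weighting by r), normalized so the
m ≥ 1 entries sum to one; the unnormalized m = 0 and Σ_{m≥1} powers are
kept so callers can judge absolute azimuthal contrast. `detect_symmetry`
returns the argmax over a window (default m ∈ [10, 51], bracketing every
order of interest while excluding low-order shape and wedge artifacts;
ties break toward the smaller order) with confidence = peak/median power.
No call is returned when (a) the confidence is below 2.0 — noise-only
annuli concentrate at peak/median ≈ 1.1–1.5 because each P(m) sums many
(r, z) circles, while genuine orders clear 2 even near the detection
floor — or (b) Σ_{m≥1} power ≤ 10⁻³ of the m = 0 power, i.e. the map is
azimuthally flat to numerical residue (a lathed map).

`lathe` computes the per-slice radial mean with anti-aliased tent-weighted
binning on a 4× oversampled r grid and interpolates it back onto the
Cartesian grid; this matches Cn symmetrization in the large-n limit
(n = 360 agrees to 2% RMS of map sd on blob-scale features) and is
idempotent to < 1% RMS of map sd. `symmetrize` averages the n rotated
copies; rotations use cubic-spline interpolation because trilinear
rotation of voxel-scale Gaussians leaves ~4% RMS error, which would swamp
the 1%-of-sd invariance tolerance this package adopts for symmetrization
contracts (cylindrical resampling and rasterization remain trilinear —
their contracts are correspondingly looser, e.g. the θ-independence of a
smooth resampled tube holds to ~5×10⁻³ of peak, not machine precision).

Radial profiles average the cylindrical map over θ and an axial slab;
`estimate_feature_radius` takes the highest interior local maximum in a
window and refines it with a 3-point parabola (sub-voxel; the collar
fixtures at 62 Å and 51 Å are recovered within ~0.1 Å at SNR 1). The
imposed-symmetry control holds: symmetrizing with arbitrary Cn
(17/26/38) moves the measured radius by far less than a voxel.

`lowpass` applies a raised-cosine rolloff one Fourier-voxel wide centred
at 1/resolution (DC passes, mean preserved; resolutions at or beyond the
2·voxel Nyquist limit are rejected). Note the identity limit of this
filter is the *finest* admissible cutoff: resolution is in Å, so larger
values remove more of the map. FSC uses shells one Fourier voxel wide
(finer is meaningless), per-shell normalized cross-correlation, and
linear interpolation for threshold crossings; 0.5 and 0.143 are named
constants. `score_ring_fit` rasterizes the model on the target grid,
applies a soft spherical mask (model extent + 3σ, 12 Å cosine edge) to
both maps, and reports the FSC = 0.5 crossing (a never-crossing curve
scores at Nyquist). Discriminating a wrong protomer count requires the
protomer spacing to exceed the comparison resolution — with 9 Å spacing
and 8 Å filtering, counts 49–53 order correctly around the true 51.

## Ring geometry and registration

`bend_to_arc` keeps protomers rigid and puts all distortion into the
interfaces: protomer k is protomer 0 rotated by 2πk/n about the axis at
radius r = n·rise/2π, so neighbour centres sit at the chord 2r·sin(π/n)
(→ rise as n grows) and the ring closes exactly. The rise is an input
(taken from the lattice transform); the acceptance fixtures derive it
from n₁ and r₁. Registration of an n-fold ring against an s-fold scaffold
is gcd arithmetic: contacts = gcd(n, s), period = n/gcd (51 vs 17 →
every 3rd protomer at 17 sites); gcd = 1 with s > 1 is flagged
incommensurate (26 vs 17).

## Bead simulation and dwell counting

The simulated motor is a unidirectional (CCW; the assay strain cannot
switch) continuous-time Poisson stepper over N equally spaced dwell
angles: exponential dwell times with mean = mean_dwell_time /
deenergization_factor (CCCP modelled purely as a rate multiplier, no
torque model), steps of 2π/N. The observed angle adds per-sample Gaussian
elastic-linkage noise; the bead sits at the parametric-angle point of a
projection ellipse plus isotropic localization noise. Defaults emulate a
1.3 µm bead on a slowed motor: N = 26, 10 ms mean dwell, linkage σ =
0.04 rad, localization σ = 10 nm on a 250 × 200 nm orbit, 1 kHz sampling
for 20 s (~77 revolutions). These noise scales are deliberately
non-trivial — together they blur the dwell comb by σ ≈ 0.06 rad, about a
quarter of the 2π/26 spacing.

Analysis pipeline: (1) direct algebraic least-squares ellipse fit
(Fitzgibbon constraint 4ac − b² = 1 in the numerically stable reduced
form); (2) angle extraction by inverting centre, orientation and axis
scaling before atan2 — skipping the correction leaves a 2-per-revolution
speed artefact, kept available for sensitivity analysis; (3) occupancy
weighting: each sample carries its time step, so slow (de-energized)
segments dominate; (4) the per-trace spectrum is the squared magnitude of
the occupancy-weighted circular moments |Σw·e^{−imθ}/Σw|² — the Fourier
coefficients of the empirical occupancy-weighted angular density, chosen
over the KDE's coefficients to avoid kernel attenuation at high
harmonics; traces combine by revolution-count weights (traces under 2
revolutions are excluded with a warning); (5) the dwell count is the
argmax over m ∈ [10, 50] with confidence = peak/median and a no-call
threshold of 8 (for a featureless spectrum the window maximum of
near-exponentially distributed powers sits near ln W/ln 2 ≈ 5× the
median); an even call n with more power at n/2 reports n/2 as an alias
candidate.

The von Mises KDE (grid 2048, κ chosen so the kernel FWHM is half a
2π/m_max dwell spacing, overridable) is used for dwell-density estimates
and for phase comparison. `phase_invariance` takes, per density pair, the
parabola-refined lag maximizing circular cross-correlation, reduced
modulo the dwell spacing 2π/N (an N-periodic density correlates equally
at every multiple of the spacing; only lattice misalignment is at issue),
and passes when every |lag| < π/N, with boundary cases within half a grid
step counted as failing.

## What the generators do and do not emulate

The phantoms are direct 3-D densities: no image formation (CTF, dose,
projection), no atomic detail, no protomer deformation, no spiral disk
geometry. The bead model has no torque–speed physics, no switching, no
back-stepping. Passing tests therefore demonstrate that the estimators
recover the parameters of data satisfying their own stated model — with
realistic noise, mismatched symmetries in one box, and an optional
missing wedge — not that they are robust to every pathology of real
micrographs or bead assays. In particular, the exhaustive symmetry sweep
(n = 7…51, noise-free) uses a 0.6-scaled protomer at 44 Å radius because
full-size blobs overlap azimuthally above m ≈ 45 and erase the
fundamental — a fixture-envelope limit, not a detector one. The noise
robustness of 17-fold detection down to whole-map SNR 0.1 is a seeded
regression bound on the standard phantom, not a universal claim.

## Problem sizes and determinism

Default sizes — 192³ standard phantom, 96³ collar fixtures, 64³ sweep
phantoms, 20 s bead traces — keep each analysis in seconds on one CPU
while leaving every detection comfortably above its confidence floor.
All randomness flows from explicit integer seeds in the specs; the replay
pipeline and the benchmark script are deterministic given their seed, and
rerunning produces bitwise-identical records.
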