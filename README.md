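# motorsym

Symmetry, stoichiometry and dwell-position analysis for bacterial
flagellar-motor structures — with synthetic generators that make every
analysis testable on a laptop, no data downloads required.

## The problem

The *Campylobacter jejuni* flagellar motor is a stack of coaxial rings with
deliberately mismatched cyclic symmetries: a C17 periplasmic scaffold, a
38-fold C-ring, a ~26-fold LP-ring bushing, and a basal disk whose
innermost ring carries 51 protomers with each concentric ring adding ~11
more. Working out those numbers from cryo-EM density maps and from
single-molecule bead assays takes a small toolbox of bespoke analyses that
this package implements as tested, reusable code:

- **Cylindrical map analysis** — resampling a density volume onto an
  (r, θ, z) grid; *lathing* (azimuthal averaging, the C∞ limit of imposing
  Cn symmetry); area-weighted azimuthal power spectra over annular regions
  `P(m) = Σ_{r,z} r·|F_m(r,z)|²`; calling the cyclic order as the dominant
  harmonic; radial density profiles with sub-voxel peak refinement;
  raised-cosine low-pass filtering; Fourier shell correlation with the 0.5
  (map–model) and 0.143 (half-map) resolution conventions.
- **Ring lattice geometry** — bending a linear oligomer repeat of rise *w*
  onto a closed ring of *n* protomers at radius `r = n·w/2π`; predicting
  concentric-ring protomer counts from circumference ratios
  `n_k = round(2π·r_k/w)`; gcd registration arithmetic between mismatched
  symmetries (a 51-ring on a C17 scaffold: contacts every 3rd protomer at
  17 sites); map–model FSC scoring of ring models.
- **Bead dwell counting** — from time-stamped x,y positions of a bead on a
  slowly rotating flagellar stub: algebraic ellipse fit of the orbit,
  inversion to motor angle, occupancy-weighted von Mises kernel density
  over angle, a weighted power spectrum at integer harmonics
  `P(m) = |Σ_i w_i e^{-imθ_i}/Σ_i w_i|²`, and the dwell count as its
  argmax, with phase-stability comparison across de-energization levels.
- **Synthetic generators** — multi-symmetry density phantoms (Gaussian-blob
  protomer rings, featureless tubes, additive noise, optional tomographic
  missing wedge) and stepping-bead trajectories (unidirectional Poisson
  stepper over N dwell angles, elastic-linkage and localization noise,
  elliptical projection).

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
fixtures. Detecting the component symmetries of the standard phantom
(192³ voxels at 2 Å, whole-map SNR 0.5):

```sh
$ python analysis/02_detect_symmetries.py
scaffold  -> C17  (peak/median 37.4)
cring     -> C38  (peak/median 74.4)
lpring    -> C26  (peak/median 72.8)
```

Each line is the argmax harmonic of the azimuthal power spectrum over that
component's annulus, with the peak-to-median confidence ratio (a flat,
featureless spectrum sits near 1 and is reported as "no call").

Counting dwell positions of a simulated 26-dwell motor across a CCCP-like
de-energization titration:

```sh
$ python analysis/05_bead_steps.py
cccp_0uM   ( 116.0 rev): 26 dwell positions (confidence 1931)
cccp_1uM   (  59.2 rev): 26 dwell positions (confidence 1699)
cccp_5uM   (  24.5 rev): 26 dwell positions (confidence 788)
pooled spectrum over 3 traces: 26 dwell positions
phase invariance across conditions: max lag 0.0021 rad (< pi/26 = 0.1208) -> phase-invariant
```

The pipeline recovers the 26 dwell angles at every slowing level, and the
dwell lattice stays put (maximum pairwise phase lag far below half a dwell
spacing), i.e. the dwell positions are phase-invariant.

The other drivers cover phantom construction (`01`), ring stoichiometry
and registration arithmetic (`03`), collar-radius recovery from lathed
radial profiles, including the imposed-symmetry control (`04`), and a
single-command replay of everything with pass/fail verdicts (`06`).

## Layout

```
src/motorsym/    library: volume, models, phantom, cylinder, fourier,
                 rings, beadsim, bead, pipeline
analysis/        numbered narrative drivers (write tables to results/)
tests/           pytest suite incl. property tests and benchmark checks
scripts/         acceptance.py (benchmark regeneration)
docs/methods.md  models, parameter choices, numerical tolerances, limits
```
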