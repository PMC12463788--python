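# Methods

`tcyspect` is a desk-scale simulation and reconstruction study of
quantitative ⁹⁹ᵐTc SPECT in the co-presence of ⁹⁰Y, the dual-isotope
situation that arises when a ⁹⁹ᵐTc-MAA scout acquisition is combined with
⁹⁰Y-microsphere radioembolization in a single session.  The package
generates a digital torso phantom, simulates multi-window projection data
per collimator, reconstructs the 140 keV ⁹⁹ᵐTc window with OSEM under three
⁹⁰Y-crosstalk compensation methods, and evaluates contrast recovery, lung
shunt fraction, noise and extrahepatic activity across noise realizations.

## Phantom model

The phantom is an elliptical water torso containing a liver (1172 mL
including two spherical tumors of 24.5 and 16.0 mL), two lungs (690 mL
total) and three extrahepatic-deposition (EHD) spheres of 8.1, 4.1 and
2.0 mL in the background volume.  Placement coordinates are package
constants approximating the physical torso phantom layout; they are not
quantitative results.  Compartments are voxelized by claiming the
`round(volume / voxel_volume)` nearest voxels to each compartment centre in
the compartment's ellipsoid metric, which matches nominal volumes to within
half a voxel (≤ 0.25 % for the liver, ≤ 3 % for the tumors at 4.8 mm pitch;
the 2 mL EHD sphere is 2 voxels at the coarse 9.6 mm test pitch, where the
half-voxel guarantee is the binding constraint).

Activities are solved analytically from the configured ratios.  With L the
whole-liver activity (normal liver + tumors), the lungs carry
`L·LSF/(1−LSF)` so that `lungs/(lungs+L) = LSF`, each EHD carries its
configured percentage of L (whole-liver denominator, consistent with the
reference EHD activities of 2.7/0.0/0.7 MBq at 98 MBq total to print
rounding), tumor concentrations are the configured multiples of the
normal-liver concentration, and everything is rescaled so the grand total is
exact.  Ground-truth metrics are computed from these solved activities, so
the configuration round-trips to machine precision regardless of grid.

Activity is uniform within each compartment; the torso water carries
attenuation (0.154 cm⁻¹) but no activity, lungs attenuate at 0.040 cm⁻¹
(narrow-beam values at 140 keV; bone and CT-derived maps are out of scope).

## System model

The Monte Carlo photon transport that a physical study relies on is
replaced by a deterministic two-component expectation model per
(isotope, collimator, energy window):

* a **primary** component carrying the distance-dependent geometric
  collimator response, `FWHM(z) = d_eff·(L + z)/L` with `L` the hole length
  and `d_eff` the hole diameter inflated by a septal-penetration factor;
* a **diffuse** component (object scatter, septal penetration,
  bremsstrahlung haze) equal to the primary projection convolved with a
  broad stationary Gaussian (⁹⁰Y: 60 mm FWHM for LEHR, 30 mm for ME/HE,
  mimicking the penetration haze that degrades LEHR images; ⁹⁹ᵐTc scatter:
  40 mm).

The projector rotates the volume per angle with a sparse bilinear rotation
operator, applies depth-dependent attenuation factors `exp(−∫μ)`, convolves
each depth plane with the primary PSF and sums along rays.  Because
rotation, blurring and attenuation are all explicit linear operators, the
**exact adjoint** is available (verified to machine precision), which OSEM
requires.  Gaussian blurs use zero-padded convolution, so counts leaving the
field of view are lost — physical, and irrelevant for interior sources.

Per-window sensitivities (cps/MBq) are packaged configuration at the order
of magnitude of clinical gamma cameras.  Three structural constraints are
built in rather than fitted:

* ⁹⁰Y bremsstrahlung is spectrally smooth, so its primary/diffuse split and
  blur are shared across windows of a collimator; consequently the ratio of
  ⁹⁰Y counts between the 140 and 226 keV windows equals the collimator's
  k-factor (0.478 LEHR, 0.632 ME, 0.745 HE) for *any* source distribution.
  The point-source calibration (`calibrate_k_factor`) closes this loop by
  simulation.
* ⁹⁹ᵐTc has no emissions above 161 keV: its 181 and 226 keV sensitivities
  are zero.
* The mean of the ⁹⁹ᵐTc 125 and 155 keV scatter-window sensitivities equals
  its 140 keV diffuse (scatter) sensitivity, making the TEW estimate
  consistent for the ⁹⁹ᵐTc scatter it is meant to absorb.

The point-source calibration geometry (water cylinder of 100 mm radius,
source centred) is a package constant.  Absolute sensitivity values of the
physical detector are not reproduced — orderings and ratios are the model's
claims, not absolute count rates.

## Acquisition and data manipulation

Measured data are independent Poisson samples per bin per window of the
expected counts (forward projection × 20 s per projection).  Every
stochastic operation takes an explicit seed recorded in the output's
provenance.  The study's data procedures are implemented as:

* **Pseudo-list-mode thinning** — per-bin binomial subsampling, emulating a
  proportionally lower activity (distributionally identical to a shortened
  acquisition, which the tests verify).
* **Synthetic dual-isotope combination** — per-bin sum of a ⁹⁹ᵐTc-only and a
  ⁹⁰Y-only set with matching metadata.  The ratio grid scales the ⁹⁰Y
  expectation by 1/2/3× of the base 1969 MBq before sampling (98 MBq ⁹⁹ᵐTc
  throughout); the labels 1:20/1:40/1:60 are treated as labels, not exact
  arithmetic constraints.
* **Bootstrap resampling** — multinomial redistribution of each window's
  total count using the original projection as the probability map; totals
  are preserved exactly.  3 bases × 25 resamples give the study's 75
  realizations (the scaled test study uses 2 × 5).

Dead time is paralyzable, `R_obs = R·exp(−R·τ)` with τ = 0.5 µs (typical
NaI camera), chosen because it is standard for gamma cameras and yields
closed-form linearity limits the tests can verify against brute-force
scans.  Ideal slopes are extrapolated from low-activity points; note that
with a NaI-typical τ the "< 1 MBq" ⁹⁹ᵐTc cut already carries percent-level
dead-time loss, visible as a small bias in the recovered slope — a real
feature of the procedure, reported as computed.

## Reconstruction and crosstalk compensation

OSEM with interleaved angle subsets and the multiplicative update

    x ← x · Aᵀ_s[ y_s / (A_s x + b_s + ε) ] / Aᵀ_s 1

where `b` holds the expected crosstalk counts.  The background enters only
the denominator — never subtracted from data — preserving Poisson
non-negativity.  ε = 1e−12 guards the division; voxels with zero subset
sensitivity are masked from the update.  Initialization is a uniform
positive image on the cylindrical field-of-view support; subset order is
fixed for determinism.  Full preset: 50 iterations × 8 subsets on a 128³
grid of 4.8 mm voxels with 120 angles; test preset: 10 × 4 on 64³ at 9.6 mm
with 60 angles.  Per-iteration snapshots are retained.

The three background estimators:

* **MC (model-based)** — reconstruct a ⁹⁰Y image from the 226 keV window
  (which carries no ⁹⁹ᵐTc) with the ⁹⁰Y system model, halt when the
  contrast-to-noise ratio increases by < 2 % over three consecutive
  iterations, and forward-project the image through the ⁹⁰Y 140 keV model in
  expectation (noise-free) mode.  The CNR is (mean hot − mean background) /
  background std — the formula is a declared package convention, with the
  liver as hot region and torso water as background.  In the physical study
  this reprojection is a Monte Carlo simulation; an expectation-mode
  projection computes the same noise-free quantity exactly in this model.
* **DEW** — scale the 226 keV counts by the collimator k-factor, per bin.
  The ⁹⁹ᵐTc scatter model stays on (the estimate covers ⁹⁰Y only).
* **TEW** — average the 125 and 155 keV windows per bin.  The estimate
  contains scattered ⁹⁹ᵐTc as well, so the model-based ⁹⁹ᵐTc scatter
  component is excluded from the forward model in this mode.

The 181 keV window can be configured as the MC/DEW estimation window but is
not part of the evaluated grid.

## Evaluation

Masks derive from the ground-truth label map: lungs and EHD masks dilated
by three voxels (3-D, 6-connected unit element applied three times), the
liver-background mask eroded by three voxels, tumor masks as spheres of the
physical tumor volume centred on the centre of mass of the top-1 %
intensity voxels within a search box of twice the tumor diameter around the
nominal centre.  LSF uses the dilated lungs and the undilated full-liver
mask.  CRC normalizes measured tumor contrast by (T/N − 1); noise is the
coefficient of variation over the liver background (N−1 convention, also
used for aggregation across realizations).

Because convergence differs per collimator and method, conditions are
compared at the iteration whose background noise is closest to that of the
Tc-only LEHR reconstruction at iteration 10 (test preset: iteration 10 of
10).  The target is recomputed from the reference reconstruction in the
same run — never hard-coded.

## Scaled study conditions

The packaged study grid (the conditions the tests run) is: 64³ grid at
9.6 mm, 60 angles, 10 iterations × 4 subsets, 98 MBq ⁹⁹ᵐTc + 1969/5909 MBq
⁹⁰Y (ratios 1:20 and 1:60), ME as the dual-isotope collimator, Tc-only LEHR
as reference, 2 Poisson bases × 5 bootstrap resamples = 10 realizations per
cell.  These sizes were chosen once as the smallest configuration at which
the ordering structure of the study is resolved against its realization
spread on a single workstation core; `analysis/04_crosstalk_study.py
--full-scale` runs the full-size grid.

## What the generator does and does not emulate

The synthetic data reproduce: the activity configuration and compartment
geometry of the physical phantom, Poisson counting statistics, per-window
spectral contamination calibrated to the printed k-factors,
distance-dependent collimator resolution, attenuation, and the
collimator-dependent severity of ⁹⁰Y crosstalk (LEHR's 140 keV ⁹⁰Y
sensitivity is ~6× ME's, so LEHR dual-isotope data are crosstalk-dominated).
They do not emulate: energy-resolved transport, detector energy resolution,
septal-hole aliasing, backscatter, CT-derived heterogeneous attenuation,
patient-geometry variability, or the absolute sensitivities of the physical
detector.  Passing tests therefore demonstrate the algorithmic structure —
estimator consistency, ordering of methods, robustness trends — not
absolute agreement with physical-scanner values, which are explicitly out
of scope.

## Numerical choices and degenerate inputs

* Rotation interpolation is bilinear; out-of-grid samples are zero.
* Attenuation line integrals count half of the emitting voxel's own μ.
* A voxel-grid sphere/ellipsoid is the N-nearest-voxels set, ties broken by
  stable sort order (deterministic).
* An empty (all-zero) estimation window yields a zero MC background with a
  logged warning rather than an error — Tc-only data are a valid input.
* `cnr_stop` returns the last iteration when the convergence run never
  completes; constant CNR histories stop at the earliest possible index.
* `matched_iteration` breaks ties toward the earlier iteration.
* Degenerate metric inputs (zero means, empty compartments) return NaN
  ("undefined-flagged") rather than raising, except where a precondition is
  structurally violated (empty masks after erosion → error).

## Known limitations

* The two-component spectral model makes DEW exactly consistent by
  construction; the physical DEW correction is only approximately so.  DEW
  performance here is therefore an upper bound on its physical behaviour.
* At the 9.6 mm test pitch the tumor-sphere measurement protocol clips 1–2
  compartment voxels, biasing even ground-truth CRC readouts a few points
  below 100 % — a partial-volume feature shared by all compared methods.
* The LSF degradation of uncorrected LEHR imaging is milder in this model
  than on a physical system, because the simulated ⁹⁰Y distribution shares
  the phantom's lung/liver structure while the physical penetration haze
  does not.
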