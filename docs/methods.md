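# Methods

This note records the models, conventions, numerical choices, and known
limitations behind `pinklaue`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Geometry model and conventions

One still (or pseudo-rotation series) is described by a crystal (unit cell
plus orthonormal orientation matrix *U*, det +1), a beam (unit propagation
direction **ŝ₀**, nominal wavelength, bandpass [λmin, λmax], optional
tabulated spectrum), a single flat detector panel, and a one-axis
goniometer. The lab frame is right-handed with the beam along +z by
default, the goniometer axis along +x, and the panel downstream at
z = distance with its inward normal facing the sample. Reciprocal vectors
are in Å⁻¹; in the Ewald construction **s₀** and **s₁** have magnitude 1/λ
(unit-direction variants are suffixed `_hat`). Pixels are 0-based and
continuous, with the center of pixel (i, j) at (i + 0.5, j + 0.5).

The reciprocal basis *B* is the standard Busing–Levy construction (a* along
x̂), so **q** = *U B* **h**, and `cell_from_B` inverts it through the metric
tensor. The wavelength placing **q** on its own Ewald sphere is
λ = −2(**q**·**ŝ₀**)/|**q**|², defined when **q**·**ŝ₀** < 0; with
**s₀** = **ŝ₀**/λ the elastic condition |**s₀** + **q**| = 1/λ then holds to
machine precision (property-tested).

Multi-panel detectors, distortion/parallax corrections and curved panels
are out of scope. Sign conventions of external programs are not guaranteed;
the JSON geometry schema documents this package's own.

## Synthetic generator

The generator emulates a benchtop-scale version of a kinematical
diffraction simulation: for each still it enumerates every reflection with
d ≥ d_min whose Ewald wavelength lies inside the spectrum support, draws a
squared structure factor per unique index from an exponential distribution
with Wilson-like mean `intensity_scale · exp(−wilson_b/(2d²))` (hashed from
the index, so the same **h** has the same F² on every image and every
harmonic path), weights it by the spectral density at its wavelength, and
applies a detection threshold.

Mosaicity and beam divergence are modeled as a per-reflection *antithetic
ensemble* (default 20 sub-rays): ± pairs of random small rotations of **q**
(rotation-angle FWHM = mosaicity) crossed with ± pairs of beam-direction
tilts (FWHM = divergence). The intensity-weighted mean of the sub-ray
centroids and wavelengths defines the true spot centroid and true
wavelength, mirroring how a physical spot centroid averages over the
mosaic-block and divergence distributions. Antithetic pairing makes the
ensemble mean free of first-order sampling bias at small ensemble size.
Gaussian centroid jitter (default 0.3 px per axis) is added on top.
Harmonic stacks — several members of one central ray simultaneously inside
the bandpass — are merged into a single observed spot whose intensity is
the exact member sum; the ground-truth table keeps one row per member with
the dominant (most intense) member marked.

Reference condition (the generator defaults): orthorhombic 34/45/99 Å cell,
180 stills at 1° steps, Gaussian spectrum of 5.5% FWHM centered on 1.05 Å
inside a 0.9–1.2 Å support, 0.1° mosaic spread, 0.1° divergence, 0.3 px
jitter, 3840² panel of 0.088 mm pixels at 200 mm. `wilson_b = 10 Å²`,
`intensity_scale = 2·10⁴` and `min_intensity = 10⁴` photons were chosen once
so that a still carries on the order of 150–220 strong spots spanning the
full resolution range — the spot count per image of a typical well-exposed
Laue still — and were not revisited.

What the generator does **not** model: pixel-level point spread,
polarization, absorption, air/water scatter profiles, per-pixel gain
calibration error, crystal slippage, or spatially varying mosaicity.
Passing tests therefore demonstrate the correctness of the *reduction
algorithms* under controlled optics, not robustness to every detector
pathology of real data. Optional image rendering (elliptical Gaussian spots
+ uniform background + Poisson noise + σ = 3 count read noise) exists for
exercising the integrator, not for spot finding.

## Wavelength assignment

Only the direction **q̂**_obs = normalize(**ŝ₁** − **ŝ₀**) of an observed
spot is wavelength-independent, so index matching happens in direction
space. Per still and per macrocycle (default 3):

1. enumerate feasible reflections (bounding box |hᵢ| ≤ ⌈length/d_min⌉,
   resolution filter, λ ∈ [λmin, λmax]; capped at 10⁷ candidates);
2. build the observed × candidate matrix of angles;
3. solve the rectangular linear sum assignment (scipy); matches worse than
   the gate are released, not forced;
4. resolve the central-ray degeneracy: all in-band harmonics of one ray
   have identical directions, so among members fitting equally well the one
   whose relaxed wavelength is nearest the spectral peak is kept (the most
   probable wavelength). The matched index may still be any harmonic when
   the spectrum does not discriminate — such errors are benign downstream
   because harmonic deconvolution treats all in-band orders of the assigned
   ray as compatible;
5. flag outliers by MCD on the 2-D centroid residuals (observed −
   predicted px at the model wavelength); the residual space is
   wavelength-free and matches what refinement later minimizes;
6. rotate *U* by the orthogonal Procrustes solution on the inlier direction
   pairs (SVD with det +1 correction). The unit cell is never touched here.

Two gates exist because two jobs exist: `capture_angle_deg` (default 1.0°)
bounds the initial orientation error the macrocycles can pull in;
`max_angle_deg` (default 0.1°) is the release gate for the output pass,
which is re-run at the final orientation so that reported indices are
feasible for the reported *U*. Assigned wavelengths are
λ = −2(**q̂**_obs·**ŝ₀**)/|*B***h**| — observed direction at the model
magnitude — which is exact for pure mosaic rotations (they preserve
|**q**|). Fewer than 6 inliers at any point raises a per-image
non-convergence error naming the image.

MCD uses exact subset search for n ≤ 12 (with the h-th-distance consistency
rescale and one reweighting step) and FAST-MCD (scikit-learn `MinCovDet`,
fixed random state) otherwise; the cutoff is the χ²(d) quantile 0.975. A
singular robust covariance degrades to an all-inlier mask with a warning —
the correct behavior on noise-free data, where residuals are identically
zero.

## Geometric refinement

Each still refines independently: Levenberg–Marquardt (scipy
`least_squares`, `method='lm'`, relative finite-difference step 10⁻⁶) on
Σ(Δx² + Δy²) over inliers, MCD refreshing the inlier set between
macrocycles (default 3), stopping when the RMSD changes by less than
10⁻⁴ px. Free parameters: 3 crystal-orientation angles; the cell lengths
and angles left free by the declared lattice family with |a| pinned
(auto-detected from the cell by default; for a cubic cell nothing but
orientation refines); and optionally 2 in-plane detector translations + 3
detector rotations. Hard constraints — bit-identical in the output — are
the detector distance, the beam direction, and |a|: with per-reflection
wavelengths free, an overall scale is unobservable, and pinning one length
in real space and one along the beam fixes it.

Inside every function evaluation each reflection's wavelength is re-derived
from the observed direction at the current model magnitude, so scattering
vectors always sit exactly on the Ewald sphere of their own wavelength.
Consequently the radial residual component vanishes on noise-free data
(tested to 10⁻⁶ px) and the fit is driven by tangential/orientational
information. Δψ — the rotation about the goniometer axis that would
superpose the model scattering direction onto the observed one — is
computed as a diagnostic only, never minimized.

For a single still the in-plane detector rotation is *exactly* degenerate
with a crystal rotation about the beam axis, and the detector tilts are
nearly absorbed by wavelength relaxation; left unrestrained, LM drifts
freely along these null directions. Detector nuisance parameters are
therefore weakly restrained to their imported values (σ = 1 mm for
translations, 0.01 rad for rotations). The restraint contributes nothing
along identifiable directions and pins the null space; crystal and cell
parameters are never restrained, so parameter-recovery accuracy is
unaffected (0.1° orientation and 0.3% cell perturbations are recovered to
< 0.005° and < 0.02% over 50 seeded noise-free trials in the acceptance
suite). Images with fewer than max(6, n_free + 2) inlier reflections are
flagged and skipped, not fatal to the series.

## Spot prediction and the KDE bandpass

Prediction enumerates the Ewald envelope at the refined geometry, reduces
harmonics to the coprime minimal index of each central ray (sign preserved,
so Friedel opposites remain distinct rays), records the absorbed harmonic
orders and multiplicity for downstream deconvolution, and keeps rays that
intersect the panel. The resolution-dependent bandpass is a Gaussian KDE
(scipy `gaussian_kde`, Scott's-rule bandwidth by default, overridable) over
the (λ, 1/d²) coordinates of the pooled strong assigned non-harmonic
reflections of the whole series — per-image training sets are too sparse.
The retention threshold is defined as a *quantile of the densities at the
training points* (default 0.01) rather than an absolute density: this makes
the cutoff scale-invariant across datasets, guarantees nesting (larger
cutoffs retain subsets), and retains at least the fraction 1 − q of the
observed population's density region by construction. Observed strong spots
always ride through regardless of their density. Training requires ≥ 20
points; fewer is a refusal with advice, not a silent fallback.

## Integration

Strong reflections get measured profiles: a plane is fit to the window
pixels outside the search radius (8 px default), the background-subtracted
positively clipped counts inside it give the intensity-weighted centroid
(the profile recenters) and the 2×2 second-moment matrix. Weak predictions
average the shape matrices of their k = 5 nearest strong profiles. The
foreground is the Mahalanobis-radius ≤ 2 region of the shape (≈ 86% of a
Gaussian spot's mass), the background the (2.5, 3.5] annulus; all three
radii and k are configurable, as is a hard pixel-radius cap. Pixels claimed
by more than one profile belong exclusively to the nearest centroid, so no
pixel is integrated twice (asserted). Background under the foreground is a
3σ-clipped least-squares plane (constant fallback for degenerate layouts);
the intensity is the background-subtracted foreground sum and

σ² = Σ_fg p + (n_fg/n_bg)² Σ_bg p

propagates Poisson counting error, with a scalar gain converting counts to
photons first (default 1.0 for the synthetic data). On rendered spots the
estimator is unbiased within 3% against the analytic Gaussian mass inside
the realized foreground ellipse, and the pull distribution (I − truth)/σ
has a standard deviation within [0.85, 1.15] over 200 seeded replicates.
Profile *fitting* (as opposed to summation), harmonic intensity
deconvolution, and per-image scale factors are out of scope.

## Ground-truth audits

Indexing correctness is strict: the signed integer triple must equal the
dominant truth member exactly; assignment to another in-band member of the
same central ray is counted separately as harmonic-of-correct (and still as
misindexed); Friedel mates count as misindexed. Audits are reported both
over all assigned rows and over refinement inliers.

Wavelength accuracy is reported after a single multiplicative correction —
the through-origin slope a = Σλₐλₜ/Σλₐ², which absorbs the monochromatic
cell-scale ambiguity — as the fraction of reflections with
|a·λ_assigned − λ_true| < 0.001 Å. Two truth semantics are supported. The
*pixel-level* semantics (used for the headline figure) evaluates the true
wavelength at the observed centroid, −2(**q̂**_obs·**ŝ₀**)·d_true: both
quantities refer to the same detector position, so centroiding noise
cancels and the comparison isolates indexing and cell-scale errors — the
appropriate analogue of auditing against an intensity-weighted per-pixel
wavelength map. The *spot-level* semantics compares against the ensemble
wavelength at the ideal centroid and convolves centroid noise into the
error: with 0.3 px jitter the error δλ ≈ cosθ·δ(2θ)/|q| exceeds 1 mÅ below
|q| ≈ 0.35 Å⁻¹, capping that fraction near 95% regardless of pipeline
quality. Both are computable; the distinction matters when quoting 99.9%-
level figures.

## Problem sizes and determinism

The acceptance benchmark uses the full 180-still reference series
(~27,000 strong spots) and completes in a few minutes on one CPU; unit
tests use 1–10 still series and a 64² detector patch for integration.
All randomness flows from explicit seeds (generator config, perturbations,
`MinCovDet` random state), and seeded runs are bit-reproducible.

## Known limitations

- Indexing from scratch is out of scope: an initial orientation within the
  capture gate (~1°) is required; larger errors (for example crystal
  slippage) may fail with a per-image non-convergence error and there is no
  recovery strategy.
- The central-ray tie-break uses only the spectrum shape; when in-band
  harmonic members are spectrally equivalent the choice is arbitrary (and
  benign for downstream harmonic deconvolution).
- Scan-varying (smoothed across images) refinement and joint multi-still
  refinement are not implemented; each still is refined independently.
- Real-data import is limited to this package's JSON/CSV/TIFF formats;
  adapters for other ecosystems' reflection files are best-effort and
  untested here.
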