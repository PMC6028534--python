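# Methods

This note records the models, conventions, parameter choices and known
limitations behind `condensinmap`, in the order the pipeline runs.

## Conventions

Arrays are indexed `(z, y, x)`; coordinate arrays are `(z, y, x)` in nm at
voxel centers with 0-based indices; CSV exports reorder to `x, y, z`.
Concentrations are nM, volumes µm³, axis lengths nm (µm for whole-cell
totals), counts in molecules. The single unit conversion used everywhere is
1 nM·µm³ = 10⁻⁹·10⁻¹⁵·N_A ≈ 0.6022 molecules (N_A = 6.02214076×10²³/mol),
defined once in `condensinmap.units` and covered by tests.

## Synthetic data

The generators emulate the statistical structure each analysis stage
assumes; they do not attempt optical realism beyond separable Gaussian
PSFs.

- **Noise**: Poisson photon noise on expected counts plus Gaussian read
  noise, qualitatively matching photon-counting APD detection. Both
  parameters are exposed; defaults are conservative. DNA-channel noise
  characteristics are not constrained by any measurement; they are plain
  parameters, not claims.
- **PSF**: separable Gaussians, σ_xy = 30 nm for STED (≈30-nm lateral
  resolving power of a 2D depletion beam), 100 nm confocal, σ_z = 250 nm
  (no axial gain in 2D STED). STED voxels default to 20 nm in xy and
  140 nm in z, matching the acquisition raster.
- **Two-compartment cells**: nested ellipsoids; the free pool fills the
  whole cell (open nuclear envelope regime), the bound pool distributes
  uniformly over chromatin; intensity = offset + concentration/slope.
  Truth masks and counts are deterministic given the geometry; only the
  noise consumes the seed.
- **FRAP movies**: the bleached and unbleached halves exchange surviving
  fluorophores so the total is conserved (U = ½ + ½·f(t), B = ½ − ½·f(t));
  an optional common multiplicative decay models acquisition
  photobleaching. Frame grid defaults to 20-s intervals, 40 frames.
- **Chromatid tubes**: centerlines are painted at sub-voxel steps and
  blurred, so intensity per unit axis length is constant and the lateral
  FWHM of a σ-radial tube is analytically 2√(2 ln 2)·σ. `tube_mask`
  produces flat-ended geometric tubes whose extent equals the arc length,
  the fixture used for axis-length oracles.
- **Spot decoration**: spots sit at equidistant arc-length stations
  (count = ⌊L/spacing⌋ + 1), optionally displaced perpendicular to the
  local tangent (so truth arc-length projections keep the exact spacing),
  thinned binomially by a detection efficiency, and rendered with
  integrated intensity = multiplicity × 3,000 AU.

## FCS-calibrated counting

Calibration is a robust (Huber, iteratively reweighted) line fit of
concentration on intensity — gross outliers in the calibration pairs do
not bias the slope. Voxelwise conversion floors negative concentrations at
zero; the same flooring applies to the bound-concentration correction,
with a flag recorded, since noise can drive `[Chr] − [Cyt]` negative.
Volumes come from voxel counts × voxel volume (no surface meshing).
Mitotic staging enters as an explicit `phase_label`; the three regimes are
open envelope (NEBD→anaphase, Eqs. above), prophase (equilibrium
correction with a metaphase-derived K_d), and post-reformation (only the
total nuclear count is identifiable). Conservation (bound + soluble =
whole-cell total) holds exactly in the open-envelope regime and is
tested.

## FRAP

Profile extraction segments chromatin by Otsu on the time-averaged DNA
channel, splits pixels along the principal axis of the mask's second
moments, excludes a 14-pixel gap around the bleach boundary, and computes
DNA-weighted protein means per frame after a Gaussian prefilter
(σ = 1 px; a stand-in for edge-preserving denoising — the contract is
denoising before extraction, and the choice is recorded here). The
difference is normalized by the conserved per-frame total,
`(F_ub − F_b)/(F_ub + F_b)` re-anchored to 1 at t = 0: without
photobleaching this equals the plain t = 0 normalization (the half-bleach
protocol conserves F_ub + F_b under exchange), and with any common
multiplicative decay on both channels it cancels the decay exactly — this
realizes the photobleaching-free property of the normalized difference.

Fitting is bounded nonlinear least squares (a ∈ [0, 1], rate > 0,
initialized at a = 0.5, rate = 1/min); only the combination κ + k_off is
identifiable, reported as the rate, with τ = 1/rate. The bootstrap
resamples cells with replacement (default n = 300) and refits the pooled
curve per resample; medians and IQRs summarize the distributions, and
failed resamples are counted and excluded. The synthetic recovery
benchmarks use 20 cells per regime at trajectory noise SD 0.05 and 45
frames, values chosen to represent a clean but realistic live-cell
experiment; the bootstrap IQR reflects sampling variability only, so the
truth-recovery test includes cell-to-cell parameter scatter, which is
what the bootstrap is for in practice.

## Chromatid axis and widths

Preprocessing removes slice-to-slice rigid drift by subpixel phase
correlation (estimated on the protein channel, applied to all channels),
interpolates z linearly to the lateral voxel size, and smooths the
protein channel with a σ = 0.5-voxel Gaussian.

Tracing slices the segmented volume orthogonally to its principal
eigenvector at 100 nm; local tangents from the coarse centroids drive a
20-nm adaptive second pass. Masks whose principal-axis aspect ratio is
below 2 are rejected as non-tubes. Three numerical safeguards matter for
unbiased arc lengths and were each validated against analytic oracles
(straight tube, quarter circle, 45° rotations):

- fine cuts are laterally bounded (default 1 µm) so a cutting plane
  cannot intersect a distant bend of the same tube;
- stations whose cross section holds fewer than half the median voxel
  count are trimmed — partial cap cuts otherwise drag centroids along the
  tube rim;
- the centroid polyline is smoothed with a 5-point moving average —
  voxel-quantization zigzag otherwise inflates the length quadratically.

The end-trim is exposed (`end_trim_nm`) and defaults to 0 so that traced
lengths equal geometric truth; analyses that must avoid end effects (the
FWHM window already requires full 2-µm support) can set it explicitly.

FWHM accumulates cross sections in a 2-µm window stepped by 200 nm,
projects along the out-of-plane direction, subtracts the profile's tail
median (10% outermost bins per side) as background, and interpolates the
half-maximum crossings linearly — 20-nm sampling is too coarse for
nearest-sample crossings. Windows without a half-max crossing are skipped
and logged. The radial profile accumulates all cross sections, finds the
reference point maximizing a 0.4×/0.6×-chromatid-width box sum,
symmetrizes the 1D profile through it, excludes radii beyond the
chromatid half-width, and computes containment quantiles on the radially
symmetric reconstruction (mass ∝ I(r)·r).

## Colocalization

Segmentation requires a voxel to exceed both the global Otsu threshold
and the local 9×9 in-plane mean (sensitivity factor 1.0). The default
nonoverlap statistic uses the symmetric difference over the geometric
mean of the per-channel counts (0% ⇔ identical masks; disjoint equal
masks give 200%, a documented boundary). The per-channel reading — the
mean of |A\B|/|A| and |B\A|/|B| — is also reported: for sparse spot
fields with coincidence fraction f it equals (1 − f)·100, and at f = 0.18
it reproduces the ~82% nonoverlap scale, whereas the symmetric statistic
is ~2(1 − f)·100 there; both are carried in `ColocResult`. The
cross-correlation subtracts per-channel means over the union of positive
voxels so offsets do not masquerade as correlation.

## Spot detection, clustering, spacing

Detection runs per z slice: an à-trous B-spline wavelet filter (order 2,
scale 4) removes background; local maxima above 3×SD of the first wavelet
plane seed maximum-likelihood (Poisson) fits of an integrated Gaussian
(σ init 2.2 px, fit radius 2 px). Three quality gates reject noise: the
fitted σ must stay within [0.5, 1.5]× the initial σ (a 5×5 window cannot
constrain broader fits), the peak amplitude must exceed the detection
threshold, and the amplitude-to-residual-scatter ratio must reach 6.
These keep the false-positive rate in pure noise at ≲1 per megapixel
while localizing bright spots to a few nm.

Clustering is DBSCAN with eps = 45 nm, minPts = 2, z scaled by 1:8. The
eps unit is a config field (`unit="nm"|"px"`); nm is the default because
the measured cluster density (16/µm, ≈62-nm spacing) is only consistent
with a sub-spacing eps — 45 detector pixels (900 nm in scaled space)
would fuse a whole chromatid into one cluster. Noise points are kept as
singleton clusters so isolated single complexes still count; input order
is neutralized by lexicographic coordinate sorting. Multiplicity is
⌈total intensity / 3,000 AU⌉ (minimum 1), so clusters that fuse several
complexes still contribute the right count per µm. Axial positions come
from continuous orthogonal projection onto the axis polyline (projecting
to the nearest vertex would quantize spacings to the station pitch and
distort the spacing distribution); NN distances use the z-scaled space of
the clustering convention by default, with a raw-coordinate option.

For end-to-end spacing recovery the localization jitter is 5 nm per
coordinate — the MLE precision of bright STED spots (σ_PSF/√N ≈ 3 nm at
~100 photons) with margin. The measurement-condition simulation in the
acceptance script places spots at the predicted 27.8/µm density with a
100-nm lateral spread (the scale implied by a ~115-nm axis-distance
median), thins to 60% efficiency, and reproduces the measured ~16
localizations/µm and ~50–56-nm median axial spacing; the residual
downward tendency of the simulated median (~52 vs 56 nm) reflects the
equidistant-placement idealization.

## Chromatid length

Channel alignment is integer-voxel cross-correlation restricted to a
350 × 350 × 600-nm neighborhood; a pair whose peak correlation
coefficient stays below 0.2 (noise-dominated) returns zero offset with a
warning. Background is the trimmed mean (drop lowest 10%, highest 50%) of
the rim — dilation by a radius-9 diamond minus erosion by a radius-7
diamond — on the slice with the most Condensin-positive voxels, with a
global-percentile fallback when the rim touches the frame. Region axis
lengths seed the slicing direction with the farthest boundary pair,
refine it once with the principal direction of first-pass centroids (the
raw pair vector tilts by up to the tube radius over the region length),
clamp the section step to the voxel pitch (sub-voxel sections alternate
between voxel layers and zigzag), trim partial cap sections and smooth the
centroid polyline. Background subtraction applies to both the numerator
and denominator sums. The estimator is exactly unbiased under constant
Condensin intensity per unit axis length; the test suite quantifies the
−50% bias incurred by regions with doubled local intensity, which is the
assumption a user must keep in mind on real data.

## Loop calculus

The genome model defaults to the hypotriploid HeLa Kyoto karyotype:
7.9 Gb over 64 chromosomes, replicated during mitosis (15.8 Gb over 128
chromatids, 123.4 Mb per chromatid). Genomic spacing of a subunit pool is
total DNA / pool size; physical spacing is total axis length / pool size;
holocomplex numbers are kleisin-limited (min of kleisin and HEAT totals);
loop sizes equal the genomic spacing of the relevant kleisin pool under
equidistant spacing and one fully extruded loop per holocomplex.
Reporting precision is one decimal for kb/nm and integers for counts; raw
values are retained. The ~450-kb prophase Condensin II loop bound is the
prometaphase CAP-H2 genomic spacing (433.5 kb) — no separate prophase
census exists. The packaged census itself is a measured-values fixture;
everything else in the table is derived from it at run time.

## Problem sizes

Defaults were chosen so the full test suite runs in about a minute and
the acceptance script in seconds on one core: synthetic cells on
~48×64×64 grids of 500-nm voxels, STED tubes of 2–12 µm at 20-nm lateral
voxels, 20 cells per FRAP regime, 128 tubes per length-estimator cell,
8 chromatid regions per spot-spacing condition. All are parameters.

## Known limitations

- Gaussian PSFs only; no depth-dependent aberrations, no deconvolution.
- The equidistant spot placement and straight/arc axes are idealizations;
  real chromatids bend, overlap, and have heterogeneous labeling.
- Only κ + k_off is identifiable from FRAP; k_on and the number of
  binding sites are not separated, and no reaction–diffusion modeling is
  attempted.
- Segmentation is threshold-based (Otsu + local mean) with manual-mask
  input supported; it replaces the manual 3D outlining a human performs
  on real STED data and will behave differently on low-contrast images.
- Passing synthetic benchmarks demonstrates correctness of the
  computations under the stated generative assumptions, not performance
  on real microscopy data.
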