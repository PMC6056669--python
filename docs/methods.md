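# Methods

This note documents the models, parameter choices and numerical
conventions behind `conetrack`, and what the synthetic validation does
and does not establish about real data.

## Acquisition model

Time-lapse data is organized as bursts of rapid frames repeated at long
intervals. The canonical protocol is 33 frames at 2-s intervals per
burst, bursts every 10 min over 30 min, at 0.211 μm/pixel. Frame
(b, f) sits at absolute time b·burst_interval + f·frame_interval.
Comet dynamics are analyzed within bursts only (comet lifetimes of
seconds are far below the 10-min burst spacing); growth-cone behavior
is scored between bursts.

## Synthetic time-lapse generator

The generator emulates the features of such recordings that the
analysis depends on, with exact ground truth.

**Cone shape and migration.** The cone is a low-order (k = 2–5)
Fourier-perturbed ellipse with the major axis along +x, joined to a
4-μm neurite stub at the rear; the stub end defines the proximal side
and gives the midline an unambiguous orientation. Defaults: base area
50 μm², elongation 1.8, boundary roughness 0.06. The whole shape
translates rigidly along +x at the migration velocity (signed;
default +0.25 μm/min, the typical size-independent extension rate of
these growth cones, displacing the centroid 2.5 μm per 10-min cycle).

**Comets.** Births follow a Poisson process at 0.02 μm⁻²s⁻¹, placed
uniformly in the cone; with the default mean lifetime of 8 s
(exponential, truncated at burst end and at the boundary) this yields a
standing density of ~0.15 μm⁻², in the range reported for these growth
cones. Speeds are log-normal, parameterized by median (default
0.11 μm/s, the wild-type median) and geometric SD (1.5); positive
support and a median-based parameterization match how the field
summarizes comet speeds. Headings are anterograde (+x) with
probability 0.85, retrograde otherwise, jittered by Gaussian angular
noise (20°). Within 2 μm of the leading edge, speeds are multiplied by
0.7 (comets near the front are slower); optionally comet *births* can
be thinned within a front zone, which reproduces the front-deficit
phenotype used in the differential-probability checks. An optional
minimum birth separation produces optically resolvable fields for
tracker-correctness fixtures.

**Rendering and noise.** The expected-photon image is a constant
cytoplasmic level (100 photons) inside the edge-softened mask plus
anisotropic Gaussian spots (amplitude 300, σ 0.4 μm along × 0.2 μm
across the motion direction — comet-like elongation; the true PSF is
not modeled). Poisson shot noise is applied to expected photons, then
additive Gaussian read noise (σ = 3), then quantization to uint16.
Non-goals: optics-accurate PSFs, photobleaching, filopodia.

**What the generator does not emulate.** Real recordings have
non-uniform cytoplasmic background, comet intensity variation,
photobleaching, focus drift and filopodial protrusions. Passing the
synthetic validation therefore establishes the correctness of the
algorithms under the stated imaging model, not the end-to-end accuracy
on arbitrary microscope data.

## Segmentation

Sobel edge detection with morphological cleanup locates the cone; a
half-maximum intensity refinement localizes its boundary:

1. optional 3×3 median despeckle (removes comet spots from the edge
   image) and Gaussian pre-smoothing (σ = 1.5 px);
2. Sobel gradient magnitude, thresholded by Otsu *in log space* over
   nonzero gradients — the log transform makes the threshold robust to
   the order-of-magnitude gap between cone-edge gradients and the much
   stronger comet-spot gradients;
3. dilation (disk r = 2), hole filling, erosion (disk r = 2), largest
   connected component;
4. boundary refinement: threshold the smoothed image at half the
   interior fluorescence level (median intensity above the Otsu
   intensity threshold) and keep the component overlapping step 3.
   For a blurred step edge this half-level crossing is the unbiased
   edge position; recovered areas are within ~2% of truth at default
   noise (Jaccard ≥ 0.97).

Morphology scalars come from `regionprops` of the mask: length/width
are the major/minor axes of the second-moment equivalent ellipse,
eccentricity from the same ellipse (axes, not bounding-box extents —
the ellipse reading is the standard one for regionprops-style
features). All outputs are in μm via the pixel size.

**Midline.** The mask is skeletonized; the skeleton's 8-connected
pixel graph is traversed for the maximum-arc-length
endpoint-to-endpoint path (double-sweep Dijkstra, exact on the
tree-like skeletons produced); the path is smoothed with a 5-point
moving average and oriented proximal→tip using the declared
neurite-entry edge of the ROI (the synthetic data declares "left").
Rotationally symmetric masks, whose skeleton collapses to a point,
degenerate to a unit segment along the major axis. On a rectangle the
midline stays within 0.5 px of the true medial axis over its middle
80%.

**Front.** The division point sits on the midline at 1/(1+1.7) ≈ 0.370
of its arc length from the tip end (the 1:1.7 rule is read as a
front:rear partition of midline arc length; the tip-side share is
1/2.7). The front is the contiguous boundary arc on the tip side of
the perpendicular through the division point, selected as the circular
run of boundary vertices containing the most-distal vertex. The tip
point is the distal midline endpoint projected along the local midline
direction onto the boundary (ray casting; falls back to the nearest
boundary vertex for concave tips). Note the operational midline is the
skeleton path, which stops a few pixels short of the boundary; the
division rule is applied to that path.

## Comet detection

Difference-of-Gaussians band-pass (σ 1 / 3 px), minus the band-pass
response of a 5×5 median-filtered copy of the frame — the median
filter removes the spots but keeps the cone body and its edge, so the
subtraction cancels the cone-edge ridge that otherwise contaminates
spot windows near the boundary. Local maxima (5×5 footprint) above a
robust threshold are kept: threshold = 6 × max(1.4826·MAD of the
filtered image inside the mask, the analytic band-pass response of
shot noise at the in-mask background level). The shot-noise floor
keeps residual background structure from masquerading as spots in
low-noise frames. Positions are refined by a positive-part weighted
centroid in a 9×9 window, after subtracting Gaussian models
(σ = 1.6 px, amplitude from the filtered peak) of neighboring spots;
duplicates within 1.5 px are merged (brightest wins). Measured
localization error at default noise is ≈ 0.08 px per axis for
resolvable comets — at the shot-noise (Cramér–Rao) limit of the
default photon budget; comets closer than ~2 σ of the spot size are
not resolvable and merge, which is an optical limit, not an algorithm
parameter.

## Trajectory linking

Stage 1 links consecutive frames by a globally optimal one-to-one
assignment (Hungarian algorithm) minimizing displacement, gated by an
adaptive search radius — clamp(3 × median per-frame displacement of
current tracks, 1.5, 6 px); initial frames use the maximum. Candidates
beyond the fluctuation radius (1.25 px) must also lie within the
forward cone (≤35° off the track's recent direction) or the backward
cone (≤15°, with magnitude ≤ 1.4 × the track's mean step). The
track's direction is the unit displacement over its last up-to-3
steps. Spots are sorted within each frame before assignment, making
linking invariant to input order.

Stage 2 closes gaps of 1–3 frames between track ends and later track
starts as a single global assignment with birth/death alternatives:
each admissible bridge (same angular gates; forward bridges must also
be speed-consistent, within 1.4 × mean step × elapsed intervals) is
priced by its squared deviation from the motion-extrapolated
reappearance point, and competes against the alternative cost of
ending one track and starting another, set from the 90th percentile of
observed frame-to-frame link distances. This keeps genuine
occlusion/dropout bridges (small deviation from extrapolation) while
rejecting death→birth coincidences. Chains of accepted bridges are
concatenated in one pass.

Tracks with fewer than 3 detections are discarded. A track is
complete-within-burst iff it first appears after frame 0 and last
appears before the final burst frame; only complete tracks contribute
birth/death distance-to-front values, since censored endpoints are not
real nucleation/catastrophe positions.

Kinematics: instantaneous speed = per-step displacement / elapsed time
(a gap-spanning step counts once, divided by the full gap duration —
no positions are invented inside gaps); lifetime = (last − first
detection) × frame interval; net path = last − first position.

**Measured performance.** On noise-free, optically resolvable fields
(birth rate 0.004 μm⁻²s⁻¹, births ≥ 2.5 μm from live comets) ≥95% of
ground-truth comets with ≥3 rendered frames are recovered as single
tracks with sub-half-pixel positions. At the study-condition density
(~0.15 μm⁻² with 0.8 × 0.4 μm spots) optical overlap at the crowded
leading edge caps single-track recovery near 60%; aggregate statistics
(speed medians, densities, distance profiles) remain accurate because
they do not require track identity across occlusions. The median
instantaneous speed is recovered within ~5% at configured medians of
0.11 and 0.20 μm/s; at 0.05 μm/s a 2-s step is only 0.47 px, and the
shot-noise localization floor inflates the measured median by ~10% —
an information-theoretic limit of the imaging model, not an estimator
deficiency (an anisotropic Gaussian maximum-likelihood fit does no
better).

## Spatial mapping

Comet-to-landmark distances are exact minimal point-to-segment
distances over the polyline (vectorized; single-vertex curves
degenerate to point distance). Path angles are measured between a
track's net path and the tip-ward midline tangent at the nearest
midline vertex (central differences on the smoothed polyline — the
local tangent, not the global axis, so curved cones classify
correctly). Classes: anterograde |θ| ≤ 45°, retrograde |θ| ≥ 135°,
lateral otherwise; thresholds are configurable since the field reports
the trichotomy without canonical cut-offs. Zero net paths have no
direction and are excluded with a warning.

The front-zone speed profile groups instantaneous speeds into 1-μm
distance-to-front bins with notch CIs. Note a survivorship effect in
any such profile (real or synthetic): fast comets terminate at the
boundary, so the sub-1-μm bin is biased slow even with no damping.

## Behavior scoring

Extension vs retraction per burst pair is scored from the projection
of tip displacement onto the earlier burst's proximal→tip axis
(midline endpoints). The dead zone of ±1 μm per 10 min absorbs
segmentation jitter (tip repeatability ≈ 0.2 μm) and stands in for the
visual scoring used in practice; at the typical migration rate
(2.5 μm per interval) labels are unambiguous. Near |v| = 0.1 μm/min
the displacement equals the dead zone and labels saturate at
"ambiguous" by construction — threshold sensitivity should be reported
when the regime matters.

## Statistics

* **Median CI**: q₂ ± 1.57·IQR/√n — the boxplot-notch formula (the
  printed form "1.57*IQRn" is read as 1.57·IQR/√n, the only reading
  consistent with its boxplot origin).
* **Rank-sum test**: two-sided Mann–Whitney; exact permutation null
  for tie-free samples with ≤20 per group, tie-corrected normal
  approximation otherwise (scipy backend). Pooled-constant input gives
  p = 1.
* **Bootstrap median-difference test**: observed statistic
  median(a) − median(b); the default null recenters both groups on
  the pooled median and resamples each from itself
  (percentile-shift), two-sided p with +1/(n_boot+1) continuity.
  A pooled-resampling null is available via `method="pooled"` but is
  ill-calibrated for groups with unequal dispersion or multimodal
  support. Measured type-I error at α = 0.05 over 1000 null pairs
  (n = 15): 0.040.
* **Holm–Bonferroni**: step-down via statsmodels; monotone, capped at
  1. (Step-down adjustment is not idempotent in general; only
  saturated sets are fixed points.)
* **Stratification**: half-open 20-μm² area bins from 10 to 170 μm²
  by default; per-bin n, median, notch CI. The sliding-window profile
  sorts observations by area, advances a 300-row window by 80 rows
  (overlap 220), draws bootstrap medians per window, assigns each
  window to the bin containing its median area and pools the bootstrap
  draws for the bin median and 2.5/97.5 percentile CI. Agreement of
  the two profiles (CI overlap per common bin) is the binning-artifact
  check.
* **Differential probabilities**: common value bins (default 25; the
  count is not canonical and is exposed in config) from the pooled
  minimum to the pooled 97th percentile (pooled, so both groups share
  support); per-group histograms normalized by total group
  observations, so the histogram mass equals the fraction of
  observations below the truncation point (≤1); differential =
  P_a − P_b per bin, with per-group bootstrap (default 1000 resamples)
  medians and 5th/95th percentile envelopes.
* **PCA**: z-scored features, sklearn decomposition; constant features
  dropped with a warning, rows with missing values dropped; features
  ranked by |PC1 loading|.

All stochastic operations take explicit seeds; zero-comet frames are
excluded from per-frame speed/distance medians but contribute 0 to
counts and density.

## Problem sizes used in validation

The test suite and the acceptance script size their simulations to
what the statistics require: speed recovery uses 50 bursts
(~2500 comets), migration recovery 4 bursts, tracker-correctness
fixtures 3 bursts × 3 seeds, bootstrap calibration 1000 null pairs,
and the geometric oracles 1000 random point/curve cases. These sizes
give sampling errors comfortably below the tolerances being asserted.

## Known limitations

* Track identity degrades with optical crowding (above); per-track
  quantities (lifetimes, net paths) are reliable only for resolvable
  comets, and comet *number* is better read as "resolvable comet
  number".
* Speed medians below ~0.08 μm/s are biased upward by the localization
  floor at the default photon budget.
* The front rule operates on the skeleton midline, which stops a few
  pixels short of the boundary; the division point is therefore
  slightly rear-shifted relative to a midline extended to the tip.
* One growth cone per ROI; multi-cone scenes must be cropped upstream.
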