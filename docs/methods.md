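# Methods

This note documents the models, conventions and numerical choices behind
rdomainscope, what the synthetic generator does and does not emulate, and
the known limitations.

## Coordinate and binning conventions

Positions are continuous nanometers. Images use half-open pixel binning
with the origin at the top-left pixel edge; x grows with column index, y
with row index. An event exactly on a pixel edge belongs to the
higher-index pixel. STORM renderings add one gray value per localization
at 10-nm pixels; confocal voxels default to 90 × 90 × 200 nm. All package
randomness flows through a single seeded `numpy.random.Generator` passed
into every operation; identical seed and configuration reproduce outputs
bit for bit.

## Synthetic scenes

A scene is a set of RD centers with per-domain stretch positions:

- **Stretch counts** follow a shifted geometric law,
  P(K = k) = p(1 − p)^(k−1) for k ≥ 1. The default p = 0.16 puts the
  median at 4 (P(K ≤ 3) = 0.407 < 0.5 ≤ P(K ≤ 4) = 0.502), matching the
  observed exponential-decay count histogram.
- **Stretch placement** is sequential rejection sampling inside a disc
  (or ball) of the configured domain diameter (default 150 nm): each new
  stretch is placed at target_nnd × U(0.95, 1.05) from a random existing
  stretch and at least 0.9 × target_nnd from all others, so the realized
  intra-domain nearest-neighbor median tracks the 63-nm target within a
  few percent. The heavy tail of the count law can exceed the packing
  capacity of a 150-nm disc at 63-nm spacing; when bounded retries
  (200/point) are exhausted the count is truncated at capacity. This
  leaves the median (4 ≪ capacity ≈ 10) and the NND statistics
  untouched; a configuration that cannot even hold two stretches
  (0.9 × target > diameter) raises a `PlacementError` naming the
  infeasible pair.
- **Solitary stretches** are placed with an exclusion radius equal to the
  default clustering reach (140 nm) around every other stretch — solitary
  by construction, so the ground-truth label is unambiguous. Their count
  realizes the configured fraction of all stretches (default 12.6%).
- **Dual-color scenes.** At Δt = 0 each domain's stretches are split
  stochastically between the channels (same domains, two label subsets),
  which reproduces a small nonzero two-channel offset from centroid
  statistics alone. At Δt > 0 every first-pulse domain receives a
  second-pulse partner at a lognormal center-to-center distance; the
  per-Δt medians default to a monotone progression
  (120 … 300 … 400 nm for 0 … 60 … 120 min) in which only the 60-min
  value (300 nm) is a measured anchor, and the geometric SD (1.4) is a
  realism choice. Partners keep their drawn distance and resample only
  the direction near field borders, so the border does not bias the
  spacing law. Confocal spacing scenes omit solitary stretches: a single
  stretch is far too dim to register as a diffraction-limited focus.

### Observable ground truth

A density-based clustering with MinPts = 2 cannot report a one-member
cluster, so a domain holding a single stretch is *observationally* a
solitary peak. `GroundTruthScene.observable_stats()` therefore expresses
the ground truth in the estimator's own observables: the median stretch
count over domains with ≥ 2 stretches (5 under the default law — the
truncated median of a median-4 law), the pooled intra-domain NND over
those domains, and a solitary fraction that counts single-stretch domains
(≈ +2 percentage points over the configured 12.6%). Recovery tests
compare against these.

## STORM simulation and QC

Each stretch emits Poisson(events_per_stretch, default 50) localizations
spread uniformly over frames — a deliberate simplification of fluorophore
switching kinetics (no duty cycles or dark states), sufficient to
exercise rendering, drift and FRC. Localization noise is isotropic
Gaussian with σ = 12 nm per axis by default (the precision value is
interpreted as 1σ, not FWHM; configurable). Photon counts default to a
lognormal with median 1000 and σ_ln = 0.5, so the 500-photon gate removes
~8% of events; the gate keeps events exactly at the threshold. Drift
models are linear or sinusoidal nm-vs-frame functions (or any callable).

**Drift correction** renders temporal blocks on a common grid, estimates
each block's displacement against the first block from the FFT
cross-correlation peak with a quadratic 3 × 3 sub-pixel fit, and
interpolates the trajectory at each event's frame. The residual re-runs
the estimator on the corrected stream and reports the largest remaining
block displacement; the acceptance gate is < 10 nm. The block length is a
required parameter (default 500 frames in the pipeline); blocks without
events inherit interpolated shifts with a warning.

**FRC** splits events into two temporal halves by stable frame order,
renders both on a common square grid, and correlates per frequency ring.
The default threshold is the 3σ curve 3/√(N_q/2) with N_q pixels in ring
q (the fixed-1/7 rule is available). Because the innermost rings hold
only a handful of pixels, both curves are smoothed with a 5-ring moving
average, and the resolution is the first downward crossing *after* the
FRC first clears the threshold (the 3σ curve exceeds 1 near the origin).
A curve that never drops below threshold resolves at the Nyquist scale
(two pixels); one that never clears it is flagged undefined and fails the
gate. The gate default is 50 nm.

## Overlay

Confocal slices are value-preserving linearly interpolated onto the
10-nm grid (a constant slice keeps its value; sums scale with the
resampling ratio — NCC downstream is intensity-invariant). Rigid
registration searches a ±5° rotation grid in 0.5° steps with parabolic
refinement; translation comes from the cross-correlation peak.
Registration is rotation + translation only (calibrated pixel sizes are
trusted). NCC is computed on the mean-subtracted overlapping support.
Substack selection takes the argmax of the per-projection NCC; ties
resolve to the lower z-start and are logged. ROIs are consumed as GeoJSON
polygons in STORM-frame pixel coordinates (headless operation; no
interactive segmentation).

## Clustering and morphometrics

Preprocessing: Perona–Malik anisotropic diffusion (4-neighbour explicit
scheme, exponential conduction, defaults 5 iterations, κ = 10,
γ = 0.15 — chosen so that sparse count images are consolidated without
merging stretches ~60 nm apart), then a 3 × 3 median filter, a global
intensity threshold (Otsu over the nonzero support when not given), and
removal of every nonzero pixel whose 8-connected component holds fewer
than 4 pixels ("connected to at least three others"; a 2 × 2 block sits
exactly at the bound).

Peaks are pixels equal to the grayscale dilation over a disc of radius 4
pixels. Two maxima that lie within one dilation radius of each other
necessarily carry equal values (each bounds the other) and merge to their
intensity-weighted centroid; maxima farther apart than the radius are
distinct peaks. Positions are reported at pixel centers in nm.

DBSCAN runs on the peak coordinates (not pixels) with Eps interpreted in
rendered pixels — 14 px = 140 nm at the default rendering; an explicit
nm override exists. With MinPts = 2 every point with a neighbor inside
the reach is core, so labels are exactly the connected components of the
reach graph; the test suite checks equivalence against a brute-force
density-reachability oracle, including border-point semantics at larger
MinPts.

Morphometrics per cluster: member count; per-member nearest co-member
distance (pooled across clusters for the summary median by default; the
per-cluster-median variant is a flag); the **horizontal Feret diameter**,
i.e. the x-axis extent of the member positions (the field's size measure
for irregular foci — on isotropic synthetic scenes this is a random
chord measure, so the maximum pairwise distance is also reported); and
the convex hull (collinear clusters flagged degenerate). The summary
Feret uses clusters of ≥ 3 members, with the ≥ 2 variant alongside. The
solitary fraction divides noise-labeled peaks by all peaks.

## Spacing

3D detection thresholds at an intensity percentile (default 99.5),
takes 26-connected components of ≥ 4 voxels and reports
intensity-weighted centroids in nm. The cross-channel NND is **directed**
(each early-pulse detection to its nearest late-pulse detection); a
mutual-nearest-pair mode exists behind a flag. All quantiles include
distances beyond 1,000 nm. Per-Δt summaries merge duplicate Δt tables
with a warning and report whether the median is monotone in Δt.

## Motion coupling

Trajectory pairs mix a shared and an independent isotropic Gaussian step
with √c and √(1−c) weights, c(d) = max(0, 1 − d/d_c), so the
per-particle step variance is independent of the coupling — mobility and
coupling are deliberately decoupled. Measurement noise of 30 nm per
frame (the tracking precision of the imaging) is added to the positions;
it is this noise that lifts the observed mean angle at contact to ~60°
rather than 0°. The default step σ of 45 nm/frame/axis is calibrated
once so that α(0) ≈ 60°, and corresponds to a plausible chromatin
mobility at 2 Hz.

Pairing keeps cross-channel track pairs whose overlap lasts 15–50 s
(longer overlaps truncate to 50 s from their start) within a maximal
mean separation; an exact bounding-box prefilter makes the candidate
scan tractable. α is undefined for zero displacements — such steps are
skipped and counted, never imputed. The pair's distance covariate is the
mean separation over the analyzed overlap (an initial-distance mode is
not needed for the synthetic studies and was left out). The two
regressions use the unbinned per-pair points (< 400 nm and > 600 nm; the
gap joins neither fit), and the transition is their exact intersection;
near-parallel lines (slope difference < 1e−6) return an explicit
no-transition result. The regression windows must bracket the
transition, so recovery studies at other cutoffs scale both cuts by
d_c/550 and sample pair distances out to 2.7 d_c — the same proportions
the default 50–1500-nm range gives a 550-nm transition. Re-analysis at a
10-s step keeps every 20th frame and reruns the identical chain.

Greedy nearest-neighbor linking (no gap closing, ties to the lower
detection index, logged) is provided for raw per-frame detections; the
synthetic trajectory simulator emits linked tracks directly.

## Combing

The stretching rate fits genomic length on combed length by least
squares, through the origin by default (zero physical length ↔ zero
genomic length; a free intercept is available since protocols can leave
offsets). Rate uncertainty comes from the fit residuals; comet
conversions propagate length × rate-SE and the residual scatter in
quadrature. The yield helper multiplies fork count × fork speed ×
duration (4 × 2 kb/min × 60 min = 480 kb, of the order of one domain's
~500 kbp).

## Problem sizes in the test and acceptance suites

The recovery suites run at territory scale: 25 domains per 6 × 6-µm
scene over 20 seeds for clustering; 8 domain pairs per 8 × 8 × 4-µm
dual-color stack over 20 seeds per spacing median; 2,000 trajectory
pairs × 40 steps over 10 seeds per coupling cutoff; 4,000 pairs × 100
steps for the resampling control; ≥ 10⁴ steps for the uncoupled-motion
null. These sizes put Monte-Carlo error comfortably inside the asserted
tolerances while a full run of the suite stays in the minutes range.

## What passing tests do and do not show

The generator reproduces the *statistical structure* the analysis
assumes — clustered emitters, Poisson blinking, Gaussian localization
error, smooth drift, Gaussian PSFs, lognormal spacings, mixture-coupled
diffusion. It does not emulate fluorophore photophysics (duty cycles,
reactivation), background or read noise, chromatic aberration between
channels, polymer linkers between domains, anisotropic or confined
chromatin motion beyond an optional confinement radius, or manual
segmentation variability. Recovery on synthetic scenes therefore
demonstrates the correctness and calibration of the estimators under the
stated model, not the biological values of real specimens.

## Known limitations

- The STORM chain is 2D (as is the imaging it models); axial drift and
  3D clustering are out of scope.
- The FRC gate applies the 3σ rule with ring-pixel counts; whether the
  original criterion used ring-pixel or half-dataset counts is an open
  convention, so the implemented formula is documented here and
  switchable (`threshold_rule`).
- Confocal deconvolution is not performed; stacks are consumed as given.
- The linker compaction and yield checks are consistency arithmetic on
  the model's parameters, not measurements.
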