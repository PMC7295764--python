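# Methods

This note documents the models, estimators, numerical choices, and
known limitations of the spheroquant pipeline, and what the phantom
benchmarks do and do not establish.

## Acquisition model and units

All computation is done in physical units — µm for length, minutes for
time — with conversion confined to the I/O layer. The emulated
acquisition is a 10X epifluorescence time-lapse: 0.65 µm/pixel (a
typical 10X-objective CCD scale; the pixel size is configurable and
never guessed — missing calibration is a hard error), one frame every
20 minutes, 109 frames (36 h). Coordinates follow the image convention:
pixel (0, 0) top-left, pixel centers, x along columns, y along rows.
Time is stored as frame index × interval rather than wall-clock to
avoid float drift.

## Spheroid sizing from radial density

The spheroid center is the intensity-weighted centroid of the
background-subtracted first frame (background: median of the darkest 5%
of pixels) and is held fixed for the whole movie, anchoring the radial
coordinate to the undissociated spheroid and avoiding feedback between
dissociation and the coordinate system.

The radial cell-density profile is the mean intensity over annuli
[r, r + Δr) (default Δr = 2 pixels; annuli open on the right; empty
annuli are flagged, never interpolated). Each profile is fitted by
nonlinear least squares to

    I(r) = A·exp(−r² / 2σ²) + B

with the constant baseline B absorbing camera offset and diffuse
background. When per-annulus pixel counts are available the fit is
weighted by them: the variance of an annulus mean scales inversely with
the number of pixels averaged, and the narrow inner annuli — which
average a handful of pixels over a handful of cells — would otherwise
dominate the residual with shot noise. Initialization tries two starts,
a half-max-radius estimate and a second-moment estimate of the excess
mass (robust when a single bright cell near the center dwarfs a broad,
dilute cloud), and keeps the lower weighted residual. Convergence
tolerance 1e-8, at most 1000 evaluations; non-converged frames are
flagged and dropped from downstream series rather than imputed (a
failed frame-0 fit is an error because it anchors the normalization).

The normalized size is σ(t)/σ(0). Note that for a 2D Gaussian cloud the
mass enclosed within radius σ is 1 − e^(−1/2) ≈ 39% — σ is defined here
strictly as the fitted scale parameter, and no enclosed-mass
interpretation is asserted.

Dissociated singles are counted as connected components of an
Otsu-thresholded frame whose centroid lies beyond k·σ₀ (default k = 3,
config-exposed) and whose area falls within single-cell bounds (default
[0.25, 6] × π·r_cell²). Two practical guards: Otsu is computed from the
pixels beyond the cutoff only (the core is orders of magnitude brighter
than a single cell and would otherwise set the threshold above
single-cell intensities), and the threshold is floored at 6 × MAD of
that region so that a frame with no real outside signal does not have
its noise split in half. Touching cells merge into one oversize
component and are excluded by the area filter — a documented
undercount, not an error.

## Motility statistics

Per-cell speed is total path length divided by elapsed time; cells
observed in fewer than two frames are excluded with a logged count.
Because cells enter tracking at different times, all statistics use
track-relative time.

The MSD is time-averaged within each cell over all start times
(overlapping windows), then pooled across cells by summing squared
displacements and pair counts per lag — equivalent to weighting each
cell's time average by its pair count. Lags are reported up to a
quarter of the shortest track duration by default; longer lags average
too few effectively independent displacement pairs to be reliable.

The diffusion coefficient comes from weighted least squares of
MSD = 4Dτ through the origin (the first-order 2D diffusion form has no
intercept; an intercept option exists but is off by default), weighted
by per-lag pair counts, with the standard error from the weighted
residuals. The 2D formula is used because tracking is 2D even though
cells move in a 3D matrix. A negative fitted slope is reported with a
warning, not clamped.

Directional statistics with respect to the flow axis (+x): Vx = net
x-displacement / elapsed time; Px = net x-displacement / path length, a
forward-migration index in [−1, 1] (zero-path cells are excluded). Px
is adopted as this conventional index; it is a convention of this
package, not a certified definition. The group-level null test is a
one-sample t-test of Vx against zero.

The detector/linker is deliberately minimal: per-frame
Laplacian-of-Gaussian spot detection (scikit-image `blob_log` on a
percentile-normalized frame) followed by greedy mutual-nearest-neighbor
linking with a displacement gate (default 4× the expected step) and no
gap closing — a track that misses a frame terminates, and tracks
shorter than a minimum length are dropped. A gate smaller than the true
step fragments tracks; this failure mode is tested, not hidden. The
linker is adequate for the sparse, well-separated cells outside a
spheroid core; it is not a replacement for LAP or Kalman trackers in
dense scenes.

## Morphology

Cells are segmented by background subtraction, Otsu thresholding,
connected components, and an area filter. Each mask is reduced to its
moment-equivalent ellipse (equal area and second central moments — the
same convention as ImageJ's Fit Ellipse); AR = major/minor axis. The
classification boundary is inclusive: AR ≥ 2.0 is mesenchymal, AR < 2.0
amoeboid. Whether ellipses should be fitted to thresholded masks or
manually outlined cells is an open choice; thresholded masks are used.

## Marker intensity

Z-stacks are sum-projected (pixelwise addition over slices), the
background — the mode of the projected histogram at unit-intensity
resolution by default, a darkest-5%-median alternative behind a flag —
is subtracted, negative residuals are clipped, and the remainder is
summed to the total intensity. The distribution reported is the
unit-area histogram (256 bins) of positive background-subtracted
pixels, pooled per condition. Consecutive confocal slices overlap by
~4.4 µm out of 13.36 µm, so totals are slightly overestimated; the bias
is reproduced on phantoms and deliberately not corrected, to match the
acquisition it emulates. Group comparison is the equal-variance
two-sample t-test (Welch's form available behind a flag); no
multiple-testing correction is applied because only single planned
comparisons are made.

## Phantom generators

**Spheroid movies.** Each core cell i has a fixed unit draw zᵢ ~ N(0, I)
and position center + σ(t)·zᵢ, so positions at every frame are an exact
sample from the isotropic Gaussian of scale σ(t), trajectories are
coherent in time, and the sampling factor cancels exactly in the
normalized size. σ(t) interpolates linearly from σ₀ (default 50 µm) to
fold·σ₀; only the endpoint matters to the recovery benchmarks, and the
linear form is the simplest monotone schedule. A detach fraction of
cells is re-seeded uniformly (by area) in the annulus [3σ₀, field edge]
and held static, so dissociated-single counts have unambiguous ground
truth. Cells are rendered as Gaussian spots (scale 5 µm, peak 100) on a
constant background (10) with additive Gaussian noise (sd 2, clipped at
zero); 300 cells per population. The rendering field for dissociation
benchmarks is 1536 px ≈ 1 mm across so the fully dissociated cloud
(σ up to ~190 µm) stays ≥ 2.5σ inside the field — truncating the
profile earlier biases the fitted σ upward.

**Trajectories.** Brownian mode draws i.i.d. per-axis steps of variance
2DΔt. Fixed-step mode draws uniform directions with exact step
magnitude, giving an exactly known frame-rate speed. The persistent
random walk (discrete Ornstein–Uhlenbeck velocity, stationary speed
scale v, persistence time P) satisfies the Fürth relation
MSD(τ) = 4D[τ − P(1 − e^(−τ/P))] with D = v²P/2; it exists for joint
realism but the recovery benchmarks calibrate speed and D separately
(fixed-step for speed, Brownian for D), because real printed speed/D
pairs imply persistence and no single memoryless process reproduces
both at once.

**Ellipse fields.** AR − 1 is lognormal within each of two mixture
components (elongated: ln(AR−1) ~ N(ln 1.8, 0.35); rounded:
N(ln 0.45, 0.40)), keeping AR ≥ 1 by construction; the mixture weight is
solved in closed form so the expected fraction with AR ≥ 2 matches any
calibration target between the two component tail probabilities.
Placement is rejection sampling on bounding circles with a retry budget.

**Z-stacks.** Each positive cell is one Gaussian spot in one slice with
pixel sum exactly equal to the nominal per-cell intensity, on a
constant per-slice background, so the total signal above background is
exactly n_cells × intensity before noise and is conserved under slice
permutation.

All randomness flows from one seeded generator per artifact; identical
seed and spec give bit-identical output, and seeds are recorded in
sidecars.

## What the benchmarks show — and what they do not

Every recovery benchmark compares a pipeline estimate against the
phantom's sidecar ground truth, never against the rendered image alone.
Recovery within tolerance establishes that the estimators are unbiased
and correctly implemented under the phantom's assumptions: isotropic
Gaussian cell clouds, memoryless or exactly-persistent walks,
non-overlapping ellipses, linear detector response, spatially uniform
background. Real assay data violates each of these to some degree —
anisotropic invasion, optical PSF and photobleaching, stage drift,
touching cells, uneven illumination are all outside the phantom model —
so passing benchmarks certify the computation, not robustness to every
imaging artifact. Optical PSF modeling, 3D reconstruction, gap-closing
tracking, and subcellular marker localization are explicit non-goals.

## Benchmark problem sizes

Speed and diffusion benchmarks use the four study cohorts (121 and 169
cells × 17 h; 107 and 46 cells × 10 h at 20-min sampling). With
pair-count weighting the 4Dτ fit is dominated by mid-range lags and
recovers D with a seed-to-seed spread of ~3–4% for the larger cohorts;
the 46-cell cohort is noisier, hence its looser (10%) tolerance, and the
acceptance tests average three independent cohorts to keep Monte-Carlo
noise well below the tolerance they assert. Size-fold benchmarks
average ten independent movies per condition; in-suite tests use
12-frame schedules (the fold estimate depends only on the endpoint
scale), while the acceptance script renders the full 109-frame movies.
Morphology benchmarks use 150-cell fields, matching the per-condition
sample size of the assay they emulate.
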