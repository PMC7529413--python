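# Methods

This note documents the statistical model, the synthetic data it is
validated against, the numerical choices, and the limitations a user
should know before applying the pipeline to real imaging data.

## The inference problem

The pipeline decides, per pixel of a nucleus-wide grid, whether one
observed variable Granger-causes another: whether past values of a
candidate cause `X1` improve prediction of a target `Y` beyond the
information already contained in `Y`'s own past and in the past of the
remaining observed variable `X2`. With three variables (optical-flow
magnitude, nearest-neighbor distance, blob area) there are six ordered
pairs; for each pair the third variable is the conditional. Detection
of Granger-causality indicates a directed predictive path, possibly via
unobserved intermediates; it is not a claim about molecular mechanism.

## Lagged models and evaluation

Each pixel contributes `N = T − P` regression rows (`T = 166` frames,
maximum lag `P = 10`, i.e. 3.6 s at 0.36 s per frame). The base model
has `k = 1 + 2P = 21` coefficients, the full model `k = 1 + 3P = 31`.
All series are z-scored per pixel (population variance) before fitting;
pixels with zero temporal variance are removed from the mask.

Fit quality is evaluated **in sample** on the same `t = P+1..T` rows
used for fitting, summarized as the adjusted
`R²_adj = 1 − (1 − R²)(N − 1)/(N − k − 1)`. In-sample evaluation makes
the raw Diebold–Mariano (DM) comparison of nested models structurally
biased: the full model's extra coefficients shrink its training error
even under the null, and at `N = 156` the naive one-sided DM test
rejects tens of percent of null pixels instead of α. The pipeline
therefore rescales each squared loss by its unbiased variance factor
`N/(N − k)` before forming the loss differential — the same
penalty-by-degrees-of-freedom logic as the adjusted R². Measured on
null simulations this restores a slightly conservative size (≈ 0.01 at
α = 0.05) while retaining ≈ 0.97 power against the reference coupling
below. The bare `diebold_mariano` function with default arguments
remains the classical test for genuine out-of-sample forecast errors
(null rejection ≈ 0.05, verified by simulation). The correction can be
disabled (`InferenceConfig.df_correct = False`) to study the
uncorrected behaviour.

The DM variance uses a Bartlett (Newey–West) window with
`hac_lags = P = 10`, tying the assumed residual autocorrelation horizon
to the model's lag order; the reference distribution is standard
normal (a Harvey-type small-sample correction is deliberately not
applied at `N = 156`). The test is one-sided (full model better) at
`α = 0.05`; no multiple-testing correction is applied across pixels —
maps report raw per-pixel decisions, and calibration is quoted as a
pixel-wise rate.

## Multi-task fitting

Because chromatin parameter fields are spatially correlated,
neighboring pixels pose similar regression problems. The per-pixel
weights are therefore fitted jointly by alternating structure
optimization: `w_l = u_l + v_l Θ` with `Θ` an `h × k` matrix with
orthonormal rows shared by all pixels, minimizing the summed squared
error plus `λ‖u_l‖²`. One alternation consists of (a) an L-BFGS-B pass
over all `(u_l, v_l)` with `Θ` fixed (vectorized objective and analytic
gradient over all pixels at once) and (b) the closed-form `Θ` update:
with the loss term depending only on `w_l`, the penalty is minimized by
the top-`h` right singular vectors of the stacked weight matrix. The
objective is non-increasing across alternations by construction;
convergence is declared at a relative objective change below 1e-8
(at most 30 alternations, warning on non-convergence).

Defaults `λ = 0.1` and `h = min(5, k)` are deliberate, exposed choices
(recorded in run metadata): λ small enough not to visibly bias
coefficients at the working SSE scale, h large enough to span the
dominant shared structure. At `λ = 0` the penalty vanishes and the fit
reproduces independent per-pixel least squares (verified to 1e-6 total
SSE); this is the oracle used in tests. Warm start: per-pixel OLS
(pseudoinverse) weights and their top singular subspace; if fewer
pixels than `h` are available the subspace is completed with an
orthonormal complement. Base and full models are optimized
independently. Rank-deficient per-pixel designs yield the minimum-norm
solution with a flag rather than an error.

## Synthetic fields: what they emulate

`generate_var_fields` produces the three co-registered series the
analysis assumes: `T = 166` points at 0.36 s on a 67.5 nm grid inside
an axis-aligned elliptical mask (the ellipse supports
distance-to-periphery profiles). Each variable is a per-pixel AR(1)
process (default `a = 0.5`, unit innovation SD) whose innovations are
Gaussian random fields, white in time and spatially correlated with a
Gaussian kernel of width 1.5 px — the simplest stationary random field
matching the spatial-correlation premise of the multi-task fit.
Spatial smoothing uses wrap-around boundaries and an exact kernel-norm
rescaling so the marginal variance is uniform. Inside a designated
causal region the effect variable receives an additional lagged term
`c · cause_{t−τ}` (reference conditions: `c = 0.5`, `τ = 3`, 200-pixel
interior region). A 50-frame burn-in precedes the recorded window, and
stationary AR initialisation removes residual transients. Optional
per-variable mean offsets inside the causal region
(`region_mean_shift`) emulate the empirically observed association of
causal regions with elevated dynamics and reduced NND; mean shifts do
not alter the z-scored dynamics used for inference.

What the generator does **not** emulate: the marginal distributions of
real flow/NND/area (innovations are Gaussian; the real quantities are
positive and skewed), blob-merging artifacts in dense regions,
measurement noise correlations between the three variables introduced
by shared segmentation, and drift of nuclei. Passing tests therefore
demonstrate correctness of the statistical machinery under its own
assumptions, not fidelity of real-data conclusions.

Coefficient recovery is assessed on the generator-scale series: after
per-pixel z-scoring, the coefficient on the cause rescales by the
cause/effect SD ratio (≈ 0.41 for the reference conditions instead of
0.5), so the injected value is only identifiable on the original scale.

## Synthetic movies and feature extraction

`generate_blob_movie` renders Gaussian spots (optionally heterogeneous
widths) with prescribed per-blob drift on a uniform background, with
Poisson shot noise plus Gaussian read noise, and emits exact blob
tables (centroid, π σ² footprint area proxy, NND, per-interval
displacement magnitude, forward convention). At desk scale, dozens of
blobs stand in for the ~10⁴ of a full nucleus.

Segmentation is a marker-assisted watershed: Gaussian smoothing
(σ = 1 px), Otsu threshold, local-maximum markers (minimum separation
3 px), watershed on the inverted smoothed image, minimum blob area
4 px². Centroids are intensity-weighted; areas are pixel counts times
the squared pitch. NND uses a KD-tree (verified against the brute-force
pairwise scan). Dense optical flow defaults to iterative Lucas–Kanade:
on spot-like images with large untextured background the TV-L1
variational solver (also available) produced strongly inflated and
poorly correlated magnitudes in known-motion tests, while ILK recovers
uniform 1-px shifts within a few percent and per-blob heterogeneous
motion with r ≳ 0.8 against ground truth. Both frames are prefiltered
with a σ = 1 px Gaussian by default because shot noise otherwise biases
magnitudes upward. Per-blob flow is the mean magnitude over the blob's
segmented footprint (the centroid-sample alternative is a one-line
change; the footprint average is less noise-sensitive).

Per-frame blob values are interpolated onto a fivefold-downsampled grid
(13.5 → 67.5 nm): linear interpolation on the Delaunay triangulation of
centroids with nearest-neighbor extrapolation outside the hull; frames
with fewer than three blobs fall back to nearest-neighbor fill with a
warning. In real mode the nucleus mask is the Otsu threshold of the
time-mean image, closed with a disk of radius 3 coarse px, largest
connected component.

## Summaries

- Causal fractions are percentages of masked, non-degenerate pixels;
  the loop diagram retains all six values and omits entries below 2 %
  only from display.
- The periphery profile bins the Euclidean distance transform of the
  mask (in µm) into 10 equal-width bins by default; empty bins report a
  missing fraction. The count-weighted mean of bin fractions equals the
  overall causal fraction (tested invariant).
- Region comparisons report the median p over 250 Wilcoxon rank-sum
  tests on subsamples of 100 pixels per group (configurable); the
  subsampling deliberately blunts significance that would come from
  pixel count alone. Groups smaller than the subsample shrink it with a
  log message; identical constant groups report p = 1 by convention.
- Lagged cross-correlations are Pearson coefficients on the valid
  overlap, with overlap-length means and SDs, for lags 0..10.

## Pipeline sizing and determinism

The default synthetic run (32×32 grid, 812 masked pixels, T = 166)
completes in well under a minute on one CPU: the nine joint ASO fits
(one full + two base per target) dominate and take a few seconds each.
Every stage funnels randomness through seeds recorded in the run
snapshot; identical configuration and seed reproduce bit-identical
fields and identical summaries. Intermediates are HDF5 (fields,
causality maps, weights), tables CSV, movies multi-page TIFF; a resumed
run reuses cached fields.

## Known limitations

- Spatial Granger-causality (predictors from neighboring pixels) is
  out of scope: with 3 variables × 10 lags × 4–8 neighbors the design
  would need 120–240 additional coefficients, which `T = 166` samples
  cannot identify (`validate_extension_cost` documents the count).
- Per-pixel decisions are not corrected for multiple testing across
  pixels; interpret maps as rate-calibrated, not family-wise.
- In-sample evaluation with the degrees-of-freedom-corrected DM test is
  a design choice, not the only defensible one; a held-out or
  cross-validated evaluation would be a natural sensitivity analysis.
- The blob-merging artifact of dense chromatin regions (apparent area
  inflation when nearby blobs fuse) is not modeled or corrected; area
  read-outs in dense regions should be treated with caution.
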