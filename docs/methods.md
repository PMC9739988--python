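# Methods

This note documents the models, parameter choices and numerical decisions
behind tilquant, and what the synthetic validation does and does not
establish.

## Stain model and deconvolution

Transmitted light through a stained section follows the Beer–Lambert law,
so per-channel optical density `OD = −log₁₀(max(I,1)/I₀)` is additive
across stains; the clamp at one intensity count bounds the OD of fully
absorbing pixels (`log₁₀ 255 ≈ 2.41` for 8-bit data) while keeping the map
monotone. The white level `I₀` defaults to the per-channel 99.9th-percentile
intensity — a robust estimate that needs no calibration target.

Per-image stain vectors are estimated by the standard automatic H&E
procedure: pixels with total OD above `od_min` (default 0.15) are projected
onto the plane of their two leading singular vectors (no centering — stain
mixtures pass through the origin in OD space), and the stain directions are
read off at the 1%/99% extremes of the angular distribution in that plane.
Hematoxylin is the vector with the larger blue-channel absorbance. The
residual direction is the normalized cross product, completing an
invertible basis; deconvolution solves the per-pixel 3×3 system and clips
negative densities. Estimation needs at least 100 foreground pixels and a
genuinely two-dimensional OD cloud; single-stain images raise a
degenerate-input error. Accuracy depends on near-pure pixels existing at
the percentile extremes: on synthetic tiles hematoxylin is recovered within
2–4°, while the faint, always-mixed cytoplasmic eosin can be off by ~10° —
which is immaterial downstream, because detection uses only the
hematoxylin channel. Whether vectors should be estimated per image or per
slide is left to the caller; the API is per-image.

## Cell detection

The detector implements the classical watershed recipe at a 0.5 µm/px
working resolution (images at other resolutions are resampled
area-preservingly): optional median filter (radius 0 = skipped), Gaussian
smoothing σ = 1.5 µm, background estimation by grayscale opening with a
disk of radius 8 µm, foreground threshold OD 0.1, watershed from regional
maxima of the background-corrected image (minimum seed separation 2 µm,
raster-scan tie-break), hole filling, then per-nucleus filters: area within
[10, 400] µm² and background value at the centroid ≤ 2 OD. Cell boundaries
grow 5 µm from each nucleus under a distance-limited Voronoi expansion, so
cells never overlap. Detections are clipped to the ROI by centroid and
ordered deterministically by (y, x).

One design choice deserves emphasis: the foreground threshold is applied to
the smoothed but *uncorrected* OD, while the background-corrected image
drives seeding and the background filter. For ordinary nuclei the opening
removes them entirely (background ≈ 0) and the two choices coincide; for
oversized structures, thresholding the corrected image would shrink a
500 µm² blob to a ~150 µm² remnant that slips past the maximum-area filter,
whereas thresholding the raw OD keeps the structure whole so the filter can
reject it — which is the filter's documented purpose.

## Features and smoothing

Per cell, intensity statistics (mean, std, min, max) of each stain are
measured in three compartments — nucleus, whole cell, cytoplasm (cell minus
nucleus; empty rings fall back to whole-cell values with a QC flag) — plus
nucleus shape: area, perimeter, circularity `4πA/P²` (clipped to 1),
eccentricity from raster moments, max/min Feret calipers from the convex
hull, cell area and nucleus/cell area ratio. Neighbourhood smoothing
replaces each feature by a Gaussian-weighted mean over cells within
`2·radius` (σ = radius/2, self-inclusive), at radii 25 µm and 50 µm by
default. The kernel is a convex combination, so smoothed values stay within
the observed range and commute with adding constants. Shape features are
smoothed along with intensity features.

## Cell classifier

A multilayer perceptron over the feature table, default one hidden layer of
8 units (`ClassifierConfig.eight_layer_preset()` gives the alternative
eight-layers-of-8 reading), trained for up to 1000 iterations with an
lbfgs optimizer — chosen because it is deterministic given the seed and
converges well at this scale. Features are z-standardized with statistics
from the training rows only. The 80/20 evaluation split is deterministic
and keyed on sorted cell ids within each class (not row positions), so the
deployed weights are a pure function of the training rows: permuting or
perturbing held-out rows cannot change them. Training refuses classes with
fewer than 10 examples (named in the error) and drops zero-variance columns
with a warning. Ties in the predicted probabilities resolve to the earliest
class in the configured list.

## TILs variables

With T lymphocytes, U tumor cells, S stromal cells and analyzed area A
(mm²): eTILs% = 100·T/(T+U), esTILs% = 100·T/(T+S), etTILs% = 100·T/total,
eaTILs = T/A. "Total" excludes IGNORE detections by default — they are
false detections and background, not cells — with
`include_ignore_in_total=True` available since the inclusive convention
also has a defensible reading for damping misclassification error.
Zero-denominator ratios are defined as 0 and QC-flagged. Multi-region
aggregation sums counts and areas and recomputes the ratios; it never
averages percentages.

## Cut-point discovery

Candidates are midpoints between consecutive sorted unique marker values;
those leaving either group below `min_group_fraction` (default 0.1) of the
cohort are skipped. For each candidate the two-group log-rank chi-square is
computed — at each distinct event time, observed minus hypergeometric
expected events, with the usual variance — and the maximizer is selected
(smallest threshold on ties). "High" includes the threshold value. The
selected statistic is maximal over many correlated tests, so the naive
p-value is anticonservative; the reported `p_corrected` uses the
Miller–Siegmund approximation over the scanned quantile band, with a seeded
permutation null available. Only two-group splits are supported.

## Survival models

Kaplan–Meier uses the product-limit estimator with linear-scale Greenwood
95% intervals clipped to [0, 1]. The Cox model maximizes the partial
likelihood by Newton–Raphson with step-halving; Efron tie handling is the
default (Breslow available). Convergence requires gradient norm < 1e-8 or a
Newton step below 1e-10 — near the optimum the log-likelihood plateaus
below float-comparison precision, and a vanishing step is the sharper
certificate. Wald intervals and p-values come from the observed
information; an ill-conditioned information matrix (condition number >
1e8, e.g. from fitting pT, pN and pTNM stage jointly) logs a warning rather
than failing, since the covariate-adjusted eTILs effect remains
well-identified. The cohort analysis battery fits univariate models for
age (≥70 vs <70), sex, pT (3–4 vs 1–2), pN (2–3 vs 0–1), pM, pTNM stage
(III–IV vs II), lymphovascular invasion and dichotomized eTILs, and one
multivariate model over age, pT, pN, pTNM, LVI and eTILs. Missing values
(including "x" stage categories) are dropped complete-case per model with a
logged count; there is no imputation.

## Synthetic data

**Tiles.** Nuclei are placed by seeded dart-throwing with a minimum
edge-to-edge separation (default 2 µm) and rendered as rotated ellipses
with radial OD profile `peak·(1−ρ²)^1.5`. Class phenotypes are invented but
chosen to mirror H&E appearance and be separable by the implemented
features: lymphocytes 20–40 µm², round, peak hematoxylin OD 0.7–0.9; tumor
nuclei 60–150 µm², pleomorphic, OD 0.45–0.65; stromal nuclei 30–80 µm²,
elongated, OD 0.3–0.45. Each nucleus carries a cytoplasmic eosin halo at
1.6× its extent. Per-pixel stain loadings pass through the standard H&E
stain matrix to intensity (`I₀·10^−OD`), with Gaussian sensor noise
(σ = 3 intensity counts) and 8-bit quantization. Because the detection
recipe places its boundary where the *blurred* OD crosses the threshold,
the rendered OD support of each nucleus is rescaled (by a cached 1-D
bisection) so that crossing happens at the nominal boundary; the truth
polygon remains the nominal ellipse. This models real nuclei whose faint
OD tails extend beyond the segmentable edge and makes generated and
detected areas agree without bias (within ±3% for mid-size, well-stained
nuclei). The default scene is a 320 µm tile with 100 tumor + 60 immune +
40 stroma cells.

What the tiles do *not* emulate: overlapping nuclei, chromatin texture,
out-of-focus regions, folds and pen marks, staining gradients within an
image, or mixed tissue architecture. Passing detection and end-to-end tests
therefore validates the algorithmic chain, not robustness to real-slide
artifacts.

**Cohorts.** The TILs score is a two-component normal mixture — by default
0.5·N(8, 2²) + 0.5·N(20, 4²) truncated to [0, 100], putting roughly half
the cohort on each side of the 13.2% change-point. Event times are
exponential with the hazard multiplied by the high/low hazard ratio for
subjects at or above the cut-point (ratio < 1 means longer survival for
high TILs) and by any configured covariate log-hazards (age ≥ 70, stage
III–IV, LVI, …). The baseline hazard is 0.04/month in the low group, giving
a median survival near 17 months, typical of muscle-invasive bladder
cancer. Censoring is independent uniform on [0, c], with c solved by
Brent's method so the expected censored fraction matches the requested
rate (default 0.4, matching roughly half the patients alive at last
follow-up in such cohorts). Clinical covariates are drawn from marginals
resembling a real MIBC cohort (76% male; pT2/3/4 ≈ 29/54/17%; stage
II/III/IV ≈ 20/40/40%).

**Paired fixture.** For end-to-end validation, each synthetic patient gets
a tile whose immune/tumor counts are the integer split closest to the
patient's eTILs% (with 120–150 cells per tile the rounding error is under
half a percentage point), so the pipeline's recovered eTILs% can be
compared to cohort truth within ±1 point.

## Validation studies and problem sizes

The acceptance script re-derives the headline quantities by parameter
recovery at sizes chosen to keep a full run around a minute on one CPU:
the cut-point study uses 100 cohorts of n=380 (the two published cohorts
total 380 patients); hazard-ratio point recovery uses single cohorts of
n=2000, where the Cox standard error (~0.05 on the log scale) is well
inside the comparison tolerance; confidence-interval coverage uses 500
replicates at n=247 (the validation cohort's size); multivariate recovery
averages 200 confounded cohorts of n=500.

One known limitation: at n=380 with 40% censoring and a 3× hazard
contrast, the argmax of the maximally selected log-rank process is
intrinsically variable — the recovered threshold lands within ±1.5
percentage points of the true change-point in about 84% of replicates
(rising to ~98% at n=1500). The median across replicates is unbiased to
within ~0.1 points. The scan itself is exact: it provably equals an
exhaustive brute-force search, and the log-rank and Cox routines match
independent implementations to 1e-8 and 1e-6 respectively.

## Numerical conventions

Coordinates are micrometres, origin at the image top-left, x rightward, y
downward, vertices at pixel centers. Detection ordering, watershed seeding
tie-breaks, classifier initialization and every simulation are
deterministic given their seeds; pipeline runs write a manifest (config
hash, seed, versions) sufficient to reproduce outputs byte-for-byte.
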