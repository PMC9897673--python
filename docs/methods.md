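# Methods

## The problem and the compositing trick

ECM-embedded acini display three dynamic phenotypes under multi-day hourly
imaging: round (stationary), local-spreading (protrusive, fixed centroid)
and tunnel-forming (the whole object translocates back and forth along a
conduit in the gel). Any single frame can be ambiguous — a tunnel-former
may look perfectly round — so the pipeline converts dynamics into static
shape: the movie is partitioned into non-overlapping windows of 12
consecutive hourly frames, and all object masks inside a window are
overlaid; the 8-connected components of this pixelwise union are the
*composite objects* analyzed downstream. A stationary acinus composites to
its own outline, a spreader to a roughened star (low form factor and
solidity), a tunnel-former to an elongated sweep (high eccentricity,
aspect ratio and Feret diameter).

Windows use stride = window (non-overlapping 12-hour blocks), matching how
interval heatmaps are reported; a trailing partial window is dropped rather
than padded, because unequal exposure would bias area and shape features.
Objects are associated within a window purely by spatial overlap of the
union — no tracking. A very fast object with zero overlap between
consecutive frames would fragment into several composites; an optional
dilation radius (default 0 px) can bridge such jumps. Composites touching
the field border are flagged and excluded from statistics by default, since
their morphometrics are truncated.

## Morphometric features

Each composite's union mask is measured with standard region properties:
eccentricity, aspect ratio (major/minor ellipse axis), major/minor axis
lengths, maximum Feret diameter, form factor 4πA/P², solidity, extent,
area and perimeter, with lengths calibrated to µm via the pixel size.
Perimeter uses the Crofton estimate, which is unbiased on rasterized smooth
shapes (plain boundary counting overestimates a disk's perimeter by ~5%,
which would push a circle's form factor to ~0.9 instead of ~1).

The feature vector is ordered with elongation descriptors first, then
compactness, then raw size. The ordering matters only for tie-breaking in
the boosting search (below): when several features split a contrast equally
well, the deterministic tie-break prefers the lower feature index, and we
want the motility signature (elongation of the composite sweep) to win such
ties over magnification- and growth-dependent size measures.

## Gentle boosting with decision stumps

The classifier is a multiclass gentle-boosting ensemble of single-feature
threshold stumps, trained one-vs-all with a shared split per round:

- Targets `y_c ∈ {+1, −1}` per class `c`; per-class weights `w_c`
  initialized uniform and renormalized each round.
- Candidate thresholds per feature are the midpoints of sorted unique
  values, quantile-subsampled to at most 256.
- Each round, for every candidate (feature, θ), the least-squares votes are
  `a_c = Σ w·y·[x>θ] / Σ w·[x>θ]` and `b_c` on the complement; the
  candidate minimizing the total weighted squared error
  `Σ_c Σ_i w_ci (y_ci − f_c(x_i))²` is kept (ties: lower feature index,
  then lower θ), and weights update multiplicatively,
  `w_ci ← w_ci · exp(−y_ci f_c(x_i))`.
- Prediction sums the stump votes per class and takes the argmax, ties
  resolving to the earlier class in (round, spread, tunnel).

Because the votes are weighted class-conditional means of ±1 targets they
are bounded in [−1, 1], which guarantees the exponential loss of the
additive model is non-increasing round over round (recorded in
`metadata["train_loss"]`). Splits depend only on value order, so any
strictly monotone per-feature transform applied consistently to train and
test data leaves predictions unchanged. Training is a pure function of the
row order, labels and hyperparameters. Default 30 rounds: the loss plateau
on the synthetic dataset is reached well before that, and more rounds only
cost time.

Validation uses stratified k-fold cross-validation (default 5 folds,
shuffled with a fixed seed). The published figure this mirrors did not
state its validation scheme or n; held-out CV on the synthetic dataset is
this package's own, conservative substitute for it.

## The simulator: what it emulates and what it does not

`synthetic_data` rasterizes minimal geometric archetypes on an hourly,
4-day acquisition grid (96 frames, dt = 1 h), with one root seed spawning
per-well child seeds (`SeedSequence.spawn`) so wells are independent and
every mask is bit-reproducible:

- **round** — a disk with i.i.d. per-frame centroid jitter;
- **spread** — a disk plus `n_protrusions` capsule-shaped protrusions at
  fixed angles whose lengths oscillate sinusoidally (24-frame period, one
  extend/retract cycle per day), centroid fixed apart from jitter;
- **tunnel** — a disk translating at constant speed along a random linear
  direction, direction flipping *before* any step that would leave
  `[0, path_len]`, so every frame-to-frame displacement is exactly
  `speed·dt` and the truth speed is recoverable to rasterization error.

Jitter is i.i.d. positional noise (not a random walk): consecutive-position
differences then have per-axis sd σ√2, giving the closed-form mean step
magnitude σ√π used as the tracking oracle. Defaults — radius 40 µm, jitter
2 µm/frame, growth 0.4%/frame, 4 protrusions of up to 35 µm, tunnel speed
20 µm/h over a 120 µm path, pixel size 1.24 µm/px (a typical 10×
wide-field calibration), with per-acinus log-normal scatter (sd 0.15–0.2
of log scale) on radius, protrusion length and speed — are this package's
choices of a realistic regime for single-cell-derived cysts; the source
assay did not publish its acquisition geometry, and none of these values
should be quoted as measured ones.

The simulator reproduces the *separability structure* of the assay
(compact vs rough vs elongated composites), not its appearance: no
photorealistic phase contrast, no z-dimension, no subcellular detail, no
ECM mechanics, no division or merging. Passing tests therefore demonstrate
that the pipeline's machinery is correct and that the classifier can
exploit composite shape; they do not measure accuracy on real movies,
where class boundaries are far blurrier. The near-perfect synthetic CV
accuracy should be read as "well above the published 92–98% band under
idealized conditions", not as a claim about real data.

`render_phase` produces a phase-contrast-like grayscale view (objects
darker than background, optional darker strip under tunnel paths, additive
Gaussian noise) sufficient to exercise segmentation and the
emphasize-track filter.

## Segmentation, outlines, emphasize-track

Segmentation of synthetic grayscale frames is deliberately simple: Otsu's
global threshold on the object-polarity image, 8-connected components,
small components (< 64 px by default) removed, labels renumbered. Outlines
follow the marching-squares 0.5-level convention on padded masks, so
polygon area tracks pixel count and boundary-touching objects still close.

The emphasize-track filter (used to visualize ECM tunnels) chains:
(1) symmetric median-deviation outlier removal over a disk neighborhood
(default radius 25 px, threshold 2 intensity units — the symmetric
bright+dark variant, since the vendor function's directional setting was
not recorded); (2) intensity inversion; (3) non-finite replacement by the
local median; (4) a configurable directional emboss ("shadow") subtraction.
Stage 4's exact original parameters are unknown; it is implemented as a
single zero-sum 3×3 kernel and treated as presentational — no quantitative
output depends on it.

## Tracking and invasion speed

Linking is greedy nearest-centroid matching between consecutive frames
(closest pairs first, one-to-one, capped at `max_link_dist`, default
50 µm), with no gap closing — adequate at the low object densities of
acinus assays, and bounded against the exhaustive minimal-cost assignment
on crossing tests. The object centroid proxies the nucleus position.

Mean invasion speed is **path-based**: the mean of consecutive-frame
displacement magnitudes divided by dt, over tracks of at least 12
consecutive frames (shorter tracks are excluded with a reason code).
Net displacement would score back-and-forth tunnel motion near zero,
contradicting the quantity's purpose. Tracks are assigned a phenotype by
majority over the composites containing them across windows; ties exclude
the track.

## Statistics

- **Proportions** are exact counts of composite objects per
  (experiment, condition, well, interval), border-flagged composites
  excluded.
- **Normalization**: well fractions are divided by the control-condition
  mean for the same experiment, interval and class (zero control mean →
  missing). **Z-scores** are computed per (experiment, class) across all
  condition × well × interval normalized values (sd 0 → missing, never
  ±inf); the cross-experiment heatmap value is the mean of per-experiment
  z-scores. This grouping is one reasonable reading of a briefly described
  procedure; it is isolated in `normalize_and_zscore` so alternatives can
  be swapped.
- **CMH**: `(Σ_k(a_k−E_k))² / Σ_k V_k` with hypergeometric `E_k, V_k`, no
  continuity correction, p from χ²(1). Strata are independent experiments;
  each stratum is the 2×2 of composite counts, condition-vs-control ×
  class-vs-rest; one test per class and interval, Bonferroni family =
  classes × intervals. Object counts (not well-level proportions) were
  chosen as the unit because the test is a count statistic; with one
  stratum the statistic reduces exactly to ((N−1)/N)·Pearson χ².
- **2×2 tables**: Pearson χ² = N(ad−bc)²/(r₁r₂c₁c₂) without Yates
  correction (this is what reproduces the published incidence p-values
  0.0397 and 0.0417 from the printed mouse counts), with Fisher's exact
  two-sided p alongside.
- **Histoscore**: 1·weak% + 2·moderate% + 3·strong% area, range 0–300,
  inputs validated to sum ≤ 100.
- The t-test defaults to equal-variance Student (Welch behind a flag) and
  Pearson r uses the t-distribution p with n−2 df; both are checked
  against permutation oracles in the tests.

The type-I-error and power properties of the CMH machinery are verified on
studies simulated at the phenotype-call level (multinomial label draws per
well): the sampling distribution of the test depends only on the counts,
so rasterizing movies for hundreds of simulated studies would add cost but
no information.

## Numerical choices and degenerate inputs

- Coordinates are pixel-centered, origin top-left; lengths live in µm and
  convert through the pixel size only at rasterization.
- Empty masks: segmentation of a constant image returns zero objects (not
  an error); feature extraction of an empty mask raises.
- A minor ellipse axis below 1 px is clamped to 1 px so aspect ratio stays
  finite on degenerate thin shapes.
- Degenerate CMH strata (a zero margin) are skipped with a warning; all
  strata degenerate is an error.
- All file formats are plain (multi-page TIFF, JSON-lines, CSV) and
  round-trip losslessly; readers reject malformed or truncated files
  rather than returning partial data.

## Problem sizes

The default validation dataset is 300 composites per class, each simulated
as a single acinus over one 12-frame window and collapsed to its composite
(~17 s to build on one CPU); statistical property suites use 100–200
simulated studies of 3 experiments × 3 wells × 100 acini at the call
level. These sizes give stable estimates (binomial se of the CV accuracy
at n = 900 is < 1 percentage point) while keeping the full test suite fast.

## Known limitations

- Synthetic-only validation; no ingestion of vendor (IncuCyte) archives.
- No gap closing, division or merge handling in tracking; no lineage
  across windows.
- The classifier is intentionally limited to threshold stumps over the
  documented feature set; no Zernike moments or alternative learners.
- 2D only; the ECM tunnel itself is rendered, not modeled.
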