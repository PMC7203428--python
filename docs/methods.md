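# Methods

## Camera model and reconstruction

Each camera is an 11-parameter direct linear transformation (DLT) relating
court coordinates (X, Y, Z), in meters, to pixel coordinates (x, y). The
world origin sits at the intersection of a lateral line (X axis) and a bottom
line (Y axis) of the court, Z up; image coordinates have their origin at the
top-left with y downward. The projective scale is normalized by fixing the
12th parameter to 1 (the "+1" in the shared denominator), so the model is

    x = (λ1·X + λ4·Y + λ7·Z + λ10) / D,   y = (λ2·X + λ5·Y + λ8·Z + λ11) / D,
    D = λ3·X + λ6·Y + λ9·Z + 1.

Calibration stacks the two linearized equations of every world↔image pair
into a 2N × 11 system solved by SVD-backed linear least squares; no nonlinear
refinement is applied. Six pairs (12 equations ≥ 11 unknowns) are the
minimum; five pairs are rejected. Radial distortion is assumed corrected
upstream — inputs are undistorted pixels.

Triangulation from q ≥ 2 views stacks the same equations with (X, Y, Z)
unknown (2q × 3) and solves in least squares; the single-view fallback fixes
Z and solves the remaining 2 × 2 system in (X, Y). Any stacked system whose
condition number exceeds 1e10 is treated as degenerate (coplanar calibration
points, near-parallel rays, singular fallback geometry); projections with
|D| < 1e−9 are rejected as at/behind the camera plane.

The squared re-projection error is (x_p − x̂)² + (y_p − ŷ)², the standard
sum-of-squares form. (Where the source formulation prints the two squared
terms adjacent without an operator, the sum is adopted: a product would
vanish whenever either coordinate happened to match, which is geometrically
meaningless.)

## Point-to-player assignment

Assignment of detected head points to players is a constrained combinatorial
problem over a binary matrix A[p, l]:

* row sums ≤ 1 — a point feeds at most one player;
* column sums in [2, w] for every localized player, with at most one point
  per camera (two views are the minimum for 3D reconstruction, and a second
  point from the same camera adds no independent ray);
* per-point squared re-projection error ≤ τ², with τ = 25 px by default
  (the same tolerance used by the evaluation protocol's matching rule);
* h_min ≤ Z ≤ h_max, defaults 1.2 m and 3.2 m — a crouching player to the
  apex of a jump.

Each feasible subset S is scored by the merged objective
score(S) = (Σ_p e_p)/q² − q with q = |S|, which embeds the preference for
more supporting views (zero-error groups score exactly −q, strictly
decreasing in q) while penalizing inconsistency. The production solver is a
constructive greedy: every *round* enumerates all feasible subsets of the
remaining points, scores each by triangulation, and localizes the global
minimum of that round; its points are removed and rounds repeat until no
feasible subset remains (optionally capped by `max_players`). Ties break by
lower score, then larger subset, then lexicographically smallest point-index
tuple, making rounds deterministic. Remaining single-view points are
localized with Z fixed to the mean head height (1.85 m default); a point
whose fixed-height system is singular is left unlocalized rather than
guessed.

The assignment matrix covers optimized (multi-view) players only; fallback
localizations sit outside the combinatorial assignment, which keeps the
column-sum invariant exact.

`brute_force_assign` is the testing oracle: the exact minimum of the summed
per-player objective over all collections of disjoint feasible subsets
(points may stay unassigned, contributing zero), found by memoized
depth-first search and guarded to ≤ 12 points. Because the greedy's own
selection is always a candidate, the oracle total never exceeds the greedy
total. On noise-free scenes with ≥ 2 m player spacing the two agree
essentially always; under 1 px detection noise the greedy's total-score
regret measures well below 1 % and its mean 3D error matches the oracle's.

## Head detection

**Background model.** A per-pixel mixture of K = 3 Gaussians over grayscale
intensity, adapted online with learning rate 1/history (default history 120
frames, which is also the burn-in length). A pixel matches a component
within 2.5 standard deviations; matched components adapt toward the pixel,
unmatched ones decay, and unmatched pixels replace the weakest component.
Components are ranked by weight and the top ones holding 70 % of the total
weight model the background. Foreground pixels whose intensity ratio to the
dominant background mean falls in [0.35, 0.90] are relabeled background as
cast shadows. The model is implemented in vectorized NumPy within this
package.

**Candidates.** The cleaned mask (3 × 3 morphological opening) is traced
with marching-squares contours. Along each closed contour, points whose
image row is a local minimum within a ±5-step window (y grows downward) are
head seeds — one per head even when several touching players share one
contour — deduplicated with 5-px non-maximum suppression. Around each seed a
Circle Hough transform (Canny edges of the foreground-masked grayscale,
radii 6–20 px by default) proposes the best circle whose center lies within
1.5 × r_max of the seed and whose accumulator clears a configurable
threshold; duplicate circles keep the stronger accumulator. Candidates
outside the per-camera interest polygon are discarded.

**Features and classifier.** Each candidate is described by a Dalal–Triggs
HOG over a 64 × 64 window: 8 × 8-px cells, 2 × 2-cell blocks at one-cell
stride, 9 orientation bins, L2-Hys normalization — 7² blocks × 4 cells × 9
bins = 1,764 features, matching the network's input width. Descriptors are
computed on the foreground-masked grayscale so they encode the player's
shape rather than incidental background texture (which block normalization
would otherwise amplify to full magnitude). The classifier is a feed-forward
network with one hidden layer of 10 logistic units trained by
back-propagation (Adam, learning rate 2e−3) on a stratified 70/15/15
train/validation/test split, with early stopping once the validation
cross-entropy has not improved for 20 epochs (best weights restored).
Candidates with head probability ≥ 0.5 become detections; the probability is
retained on each detection.

## Synthetic study conditions

The generator emulates the acquisition geometry the pipeline targets: one
half of a basketball court (14 × 15 m), w = 3 static cameras mounted ~12 m
above the floor around the court perimeter, aimed at the playing volume and
producing nominal 1,038 × 776 px frames. Cameras are synthesized directly as
DLT parameter vectors from a pinhole composition (look-at extrinsics times
intrinsics whose focal length is chosen so the whole court volume stays in
frame), so geometry tests do not depend on the DLT fitter. Player heads are
uniform over the court with heights in 1.65–1.95 m and a default 2 m minimum
spacing; detections get isotropic Gaussian pixel noise (σ = 1 px default),
optional per-(player, camera) misses, and uniform outlier clutter.
Everything is deterministic under a fixed seed.

The renderer draws a smooth seeded floor texture, players as a dark body
ellipse (head-to-floor axis) topped by a bright circular head centered
exactly on the projected head point with projection-consistent radius, and
optional half-luminance floor shadows. It emulates what the detection stage
needs — stable background, head-shaped foreground, shadow contrast — and
deliberately omits jersey texture, limb articulation, spectators, and
photometric effects (glare, motion blur); passing detection tests therefore
demonstrates the machinery end to end on controlled imagery, not performance
on broadcast video. Classifier training data is harvested from rendered
ground truth: positives centered on heads (plus ≤ 2 px jittered copies —
still "centered" at rasterization scale), negatives from off-center heads at
uniform directions (so body-top circles straight below a head are
represented), random crops, and hard negatives mined by running the circle
fitter itself on the training render.

Image-level tests run on a 7 × 7.5 m playing region at 520 × 388 px with a
40-frame background history and a 0.16 m head radius, giving ~6 px rendered
heads — the same head-to-frame proportion as nominal-resolution footage at a
quarter of the pixel count; assignment-level checks use 200 noise-free
scenes, 500 noisy frames, and 50 recovery scenes. These sizes are the
package's test-scale choices; every threshold asserted by the tests
(agreement ≥ 95 %, regret ≤ 5 %, true detections ≥ 90 %, false positives
≤ 5 %, pixel RMSE ≤ 3 px, classifier accuracy ≥ 95 %) refers to these
synthetic conditions.

## Evaluation protocol

A detection is *true* when it lies within 25 px of a ground-truth head
(greedy distance-sorted one-to-one matching; Hungarian matching available
behind a flag). Unmatched detections are false positives; unmatched truths
are misdetections. All three rates share the denominator
true + false positives + misses, so they sum to 100 % whenever defined.
Localization error is RMSE of the Euclidean distance over matched pairs, on
the court plane (XY) or in space (XYZ).

## Known limitations

* No temporal linking: frames are solved independently; trajectories and
  identity persistence are out of scope.
* The greedy heuristic is exact per round, not jointly; the bundled oracle
  bounds the gap on small instances only.
* The fallback inherits the full bias of the height prior: a player jumping
  or crouching while seen by one camera is displaced along the viewing ray
  (fallback RMSE is roughly 4–5× the multi-view RMSE under the default
  conditions).
* The background model assumes static cameras and near-static illumination;
  the renderer does not exercise abrupt lighting changes.
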