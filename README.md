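# hooploc

Video-based 3D localization of multiple basketball players from synchronized,
static multi-camera views — for sports scientists and performance analysts who
need non-invasive 3D position data (including the vertical component that
matters for jumps) during real games, without markers or wearables.

## What it does

The pipeline has two stages.

**1. Head detection (per camera).** The player's head is used as the
reference point — it is far more stable under occlusions, floor reflections
and cast shadows than feet or bounding-box bottoms. Each camera's frames pass
through an adaptive Gaussian-mixture background model with shadow relabeling,
morphological opening, contour tracing, and a Circle Hough search for
head-sized circles near the topmost points (local maxima) of each foreground
contour. Every candidate circle is described by a Histogram of Oriented
Gradients over a fixed 64 × 64 window (1,764 features) and classified
head / non-head by a small feed-forward network (one hidden layer of 10
logistic units, trained by back-propagation with a 70/15/15
train/validation/test split). Only candidates inside a per-camera interest
polygon are considered.

**2. 3D reconstruction (across cameras).** Each camera k is an 11-parameter
direct linear transformation (DLT) λ₁ᵏ…λ₁₁ᵏ:

    x = (λ₁X + λ₄Y + λ₇Z + λ₁₀) / (λ₃X + λ₆Y + λ₉Z + 1)
    y = (λ₂X + λ₅Y + λ₈Z + λ₁₁) / (λ₃X + λ₆Y + λ₉Z + 1)

calibrated by linear least squares from ≥ 6 surveyed court↔image point pairs
(each pair gives two equations for the 11 unknowns). Which detected point
belongs to which player is unknown, so association is posed as a constrained
combinatorial optimization over a binary assignment matrix A[p, l]: each point
feeds at most one player; each player uses 2…w points, at most one per camera;
every used point must re-project within a pixel tolerance τ (default 25 px);
and the reconstructed height must satisfy h_min ≤ Z ≤ h_max. Candidate groups
are scored by the merged objective

    score(S) = ( Σ_p e_p ) / q² − q ,     q = |S|,  e_p = squared re-projection error,

which trades re-projection consistency against the number of supporting
views (a perfectly consistent q-view group scores −q). The solver is a
constructive greedy: each *round* exhaustively scores every feasible subset of
the remaining points, triangulates the best one as the next player, removes
its points, and repeats until nothing feasible remains. Leftover single-view
points are localized by fixing Z to the mean player height (1.85 m default)
and solving the resulting 2 × 2 system. An exact joint solver over disjoint
subsets (`brute_force_assign`) serves as a testing oracle on small instances.

A deterministic synthetic-scene generator (camera rigs over a 14 × 15 m half
court with cameras ~12 m high, noisy detections, rendered image sequences
with ground truth) makes every stage testable without any game footage.

## Worked example

```python
from hooploc import SceneConfig, OptimizationConfig, make_scene, localize_frame

scene = make_scene(SceneConfig(n_players=3, noise_px=1.0, seed=7))
locs, A = localize_frame(scene.detections, OptimizationConfig())
for l in locs:
    p = l.position
    print(f"{l.label} {l.method} q={l.n_points} score={l.score:+.3f} "
          f"({p.X:.2f}, {p.Y:.2f}, {p.Z:.2f})")
```

prints

```
0 optimized q=3 score=-2.936 (10.77, 12.65, 1.76)
1 optimized q=3 score=-2.310 (4.73, 14.29, 1.68)
2 optimized q=3 score=-2.240 (6.19, 5.74, 1.64)
```

Three players were simulated at (4.75, 14.32, 1.75), (10.75, 12.68, 1.77) and
(6.19, 5.72, 1.68) with 1 px detection noise in three cameras; all three are
recovered by optimization (three supporting views each, scores close to the
ideal −3) within a few centimeters. The same pipeline runs from the shell:

```
hooploc simulate --players 3 --frames 2 --seed 7 --out-dir demo
hooploc localize --detections demo/detections.csv --cameras demo/cameras.json --out demo/locs.csv
hooploc evaluate --localizations demo/locs.csv --truth demo/truth.csv --out demo/metrics.json
```

which, in this noise-free default, reports planar and spatial RMSE ≈ 4 × 10⁻⁹ m
over 6 matched players. `hooploc calibrate` fits DLT cameras from a
correspondence CSV and `hooploc detect` runs the image stage over per-camera
frame directories.

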