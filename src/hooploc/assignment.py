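"""Constrained combinatorial assignment of detected head points to players.

Given head candidate points detected independently in each of ``w`` calibrated
camera views, the task is to decide which points across views belong to the
same player and to triangulate those groups. The association is modeled by a
binary assignment matrix ``A[p, l]`` (point p attributed to player l) under
the constraints:

* each point feeds at most one player (row sums <= 1);
* each localized player uses between 2 and w points, at most one per camera
  (two views are the minimum for 3D reconstruction);
* every used point re-projects within a pixel tolerance tau of the
  triangulated head (per-point squared error <= tau^2);
* the reconstructed head height lies within plausible bounds
  h_min <= Z <= h_max.

Each candidate group ("subset") is scored by a merged objective that trades
re-projection consistency against the number of supporting views::

    score(S) = (sum of squared per-point re-projection errors) / q^2  -  q

with q = |S|; a perfectly consistent q-view group scores -q, so groups with
more consistent views win. The full joint problem is exponential, so the
production solver is a constructive greedy: each *round* exhaustively scores
every feasible subset of the remaining points, localizes the best-scoring one
as the next player, removes its points, and repeats until no feasible subset
is left. Leftover single-view points are localized by the fixed-mean-height
fallback. An exact joint solver over disjoint subsets (`brute_force_assign`)
is provided as a testing oracle for small instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DegenerateGeometryError, DegenerateProjectionError, ProblemSizeError
from .geometry import (
    CameraModel,
    ImagePoint,
    WorldPoint,
    reprojection_error,
    triangulate,
    triangulate_fixed_height,
)

#: Instance-size guard for the exhaustive joint oracle.
BRUTE_FORCE_MAX_POINTS = 12


@dataclass(frozen=True)
class Detection:
    """One candidate head point in one camera image."""

    point_index: int
    camera_id: int
    image: ImagePoint
    score: Optional[float] = None


@dataclass
class DetectionSet:
    """All candidate head points of one frame, plus the camera rig."""

    frame_id: int
    detections: list[Detection]
    cameras: list[CameraModel]

    def __post_init__(self):
        indices = [d.point_index for d in self.detections]
        if len(indices) != len(set(indices)):
            raise ValueError("detection point_index values must be unique within a frame")

    @property
    def n_cameras(self) -> int:
        return len(self.cameras)

    def camera(self, camera_id: int) -> CameraModel:
        for cam in self.cameras:
            if cam.camera_id == camera_id:
                return cam
        raise KeyError(f"no camera with id {camera_id}")

    def by_camera(self) -> dict[int, list[Detection]]:
        out: dict[int, list[Detection]] = {}
        for det in sorted(self.detections, key=lambda d: (d.camera_id, d.point_index)):
            out.setdefault(det.camera_id, []).append(det)
        return out


@dataclass(frozen=True)
class OptimizationConfig:
    """Constraint parameters of the assignment problem.

    tau_px
        Maximum tolerated per-point re-projection error, pixels. The squared
        constraint is e_p <= tau_px**2.
    h_min, h_max
        Plausible head-height band in meters (crouching to jump apex).
    mean_height
        Height prior used by the single-view fallback, meters.
    max_players
        Optional cap on the number of greedy rounds (None = until infeasible).
    """

    tau_px: float = 25.0
    h_min: float = 1.2
    h_max: float = 3.2
    mean_height: float = 1.85
    max_players: Optional[int] = None

    def __post_init__(self):
        if self.tau_px <= 0:
            raise ValueError("tau_px must be positive")
        if not (self.h_min < self.mean_height < self.h_max):
            raise ValueError("require h_min < mean_height < h_max")


@dataclass
class PlayerLocalization:
    """One localized player: court position, supporting points, and score."""

    label: int
    position: WorldPoint
    detections: list[Detection]
    squared_errors: list[float]
    score: float
    method: str  # "optimized" | "fallback"

    @property
    def n_points(self) -> int:
        return len(self.detections)


@dataclass
class AssignmentMatrix:
    """Binary m x n matrix linking point indices (rows) to optimized players
    (columns). Fallback localizations are not columns: they sit outside the
    combinatorial assignment."""

    point_indices: list[int]
    entries: np.ndarray  # (m, n) of {0, 1}

    def validate(self, detections: DetectionSet) -> None:
        A = self.entries
        if A.size == 0:
            return
        if not np.isin(A, (0, 1)).all():
            raise ValueError("assignment entries must be binary")
        if (A.sum(axis=1) > 1).any():
            raise ValueError("a point is assigned to more than one player")
        col = A.sum(axis=0)
        w = detections.n_cameras
        if ((col < 2) | (col > w)).any():
            raise ValueError(f"player column sums must lie in [2, {w}]")
        cam_of = {d.point_index: d.camera_id for d in detections.detections}
        for l in range(A.shape[1]):
            cams = [cam_of[self.point_indices[p]] for p in np.flatnonzero(A[:, l])]
            if len(cams) != len(set(cams)):
                raise ValueError("a player uses two points from the same camera")


@dataclass(frozen=True)
class SubsetScore:
    """Triangulation result and merged-objective score of one feasible subset."""

    point_indices: tuple[int, ...]
    position: WorldPoint
    score: float
    squared_errors: tuple[float, ...]


def merged_score(squared_errors: Sequence[float], q: int) -> float:
    """Per-player merged objective: (sum of squared errors) / q**2 - q.

    Zero-error groups score exactly -q, so the objective strictly prefers
    more consistent supporting views; error only dilutes that preference.
    """
    return float(sum(squared_errors)) / q**2 - q


def enumerate_feasible_subsets(detections: DetectionSet) -> list[tuple[int, ...]]:
    """All point subsets that could form one player, in deterministic order.

    A subset takes at most one point per camera and between 2 and w points.
    Ordering: camera combinations by ascending size then lexicographic camera
    ids, then the cartesian product of each camera's points by point index.
    """
    groups = detections.by_camera()
    cam_ids = sorted(groups)
    subsets: list[tuple[int, ...]] = []
    for size in range(2, len(cam_ids) + 1):
        for cams in itertools.combinations(cam_ids, size):
            for choice in itertools.product(*(groups[c] for c in cams)):
                subsets.append(tuple(d.point_index for d in choice))
    return subsets


def score_subset(
    subset: Sequence[int],
    detections: DetectionSet,
    config: OptimizationConfig,
) -> Optional[SubsetScore]:
    """Triangulate one subset and evaluate the merged objective.

    Returns None (infeasible) when triangulation is degenerate, any point
    re-projects worse than tau^2, or the height falls outside [h_min, h_max].
    """
    by_index = {d.point_index: d for d in detections.detections}
    members = [by_index[p] for p in subset]
    obs = [(detections.camera(d.camera_id), d.image) for d in members]
    try:
        world, _ = triangulate(obs)
    except (DegenerateGeometryError, DegenerateProjectionError):
        return None
    if not (config.h_min <= world.Z <= config.h_max):
        return None
    try:
        sq_errors = [
            reprojection_error(detections.camera(d.camera_id), world, d.image) for d in members
        ]
    except DegenerateProjectionError:
        return None
    tau_sq = config.tau_px**2
    if any(e > tau_sq for e in sq_errors):
        return None
    score = merged_score(sq_errors, len(members))
    return SubsetScore(tuple(subset), world, score, tuple(sq_errors))


def solve_round(
    detections: DetectionSet, config: OptimizationConfig
) -> Optional[SubsetScore]:
    """One greedy round: the exact best feasible subset of the current points.

    Enumerates every feasible subset and returns the minimum-score one, or
    None when nothing is feasible. Ties break toward the larger subset, then
    the lexicographically smallest point-index tuple, so rounds are
    deterministic.
    """
    best: Optional[SubsetScore] = None
    best_key = None
    for subset in enumerate_feasible_subsets(detections):
        scored = score_subset(subset, detections, config)
        if scored is None:
            continue
        key = (scored.score, -len(scored.point_indices), scored.point_indices)
        if best_key is None or key < best_key:
            best, best_key = scored, key
    return best


def localize_frame(
    detections: DetectionSet, config: OptimizationConfig
) -> tuple[list[PlayerLocalization], AssignmentMatrix]:
    """Localize every player in one frame: greedy rounds, then fallback.

    Rounds run until no feasible subset remains (or ``max_players`` is hit);
    each round's points are removed before the next. Every leftover point is
    then localized alone by fixing Z to the configured mean head height;
    points whose fixed-height system is singular are reported in no
    localization rather than guessed.
    """
    by_index = {d.point_index: d for d in detections.detections}
    remaining = dict(by_index)
    localizations: list[PlayerLocalization] = []
    label = 0

    while config.max_players is None or label < config.max_players:
        current = DetectionSet(
            detections.frame_id, list(remaining.values()), detections.cameras
        )
        best = solve_round(current, config)
        if best is None:
            break
        members = [remaining.pop(p) for p in best.point_indices]
        localizations.append(
            PlayerLocalization(
                label=label,
                position=best.position,
                detections=members,
                squared_errors=list(best.squared_errors),
                score=best.score,
                method="optimized",
            )
        )
        label += 1

    for p in sorted(remaining):
        det = remaining[p]
        cam = detections.camera(det.camera_id)
        try:
            world = triangulate_fixed_height((cam, det.image), config.mean_height)
        except DegenerateGeometryError:
            continue
        err = reprojection_error(cam, world, det.image)
        localizations.append(
            PlayerLocalization(
                label=label,
                position=world,
                detections=[det],
                squared_errors=[err],
                score=err,
                method="fallback",
            )
        )
        label += 1

    matrix = _build_matrix(detections, localizations)
    matrix.validate(detections)
    return localizations, matrix


def _build_matrix(
    detections: DetectionSet, localizations: Sequence[PlayerLocalization]
) -> AssignmentMatrix:
    point_indices = sorted(d.point_index for d in detections.detections)
    row_of = {p: i for i, p in enumerate(point_indices)}
    optimized = [loc for loc in localizations if loc.method == "optimized"]
    A = np.zeros((len(point_indices), len(optimized)), dtype=int)
    for col, loc in enumerate(optimized):
        for det in loc.detections:
            A[row_of[det.point_index], col] = 1
    return AssignmentMatrix(point_indices, A)


@dataclass
class BruteForceResult:
    """Globally optimal joint assignment of one frame (testing oracle)."""

    assignment: AssignmentMatrix
    total_score: float
    players: list[PlayerLocalization]


def brute_force_assign(
    detections: DetectionSet, config: OptimizationConfig
) -> BruteForceResult:
    """Exact joint optimum over all collections of disjoint feasible subsets.

    Minimizes the summed per-player merged objective; points may stay
    unassigned (contributing zero). Exponential — guarded to at most
    ``BRUTE_FORCE_MAX_POINTS`` points; intended as a test oracle, not for
    production frames.
    """
    m = len(detections.detections)
    if m > BRUTE_FORCE_MAX_POINTS:
        raise ProblemSizeError(
            f"exhaustive assignment limited to {BRUTE_FORCE_MAX_POINTS} points, got {m}"
        )

    feasible = [
        s
        for subset in enumerate_feasible_subsets(detections)
        if (s := score_subset(subset, detections, config)) is not None
    ]
    containing: dict[int, list[SubsetScore]] = {}
    for s in feasible:
        for p in s.point_indices:
            containing.setdefault(p, []).append(s)

    memo: dict[frozenset, tuple[float, tuple[SubsetScore, ...]]] = {}

    def solve(available: frozenset) -> tuple[float, tuple[SubsetScore, ...]]:
        if not available:
            return 0.0, ()
        if available in memo:
            return memo[available]
        p = min(available)
        # Option 1: leave point p unassigned.
        best_score, best_sel = solve(available - {p})
        # Option 2: assign p through any feasible subset fully inside `available`.
        for s in containing.get(p, ()):
            if not available.issuperset(s.point_indices):
                continue
            sub_score, sub_sel = solve(available - set(s.point_indices))
            total = s.score + sub_score
            if total < best_score - 1e-12:
                best_score, best_sel = total, (s,) + sub_sel
        memo[available] = (best_score, best_sel)
        return best_score, best_sel

    all_points = frozenset(d.point_index for d in detections.detections)
    total, selection = solve(all_points)

    by_index = {d.point_index: d for d in detections.detections}
    players = [
        PlayerLocalization(
            label=i,
            position=s.position,
            detections=[by_index[p] for p in s.point_indices],
            squared_errors=list(s.squared_errors),
            score=s.score,
            method="optimized",
        )
        for i, s in enumerate(sorted(selection, key=lambda s: s.score))
    ]
    matrix = _build_matrix(detections, players)
    matrix.validate(detections)
    return BruteForceResult(assignment=matrix, total_score=total, players=players)
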