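"""Evaluation protocol: detection matching, rates, and localization RMSE.

A detection is *true* when it lies within a pixel threshold (25 px by
default) of a ground-truth head; detections without a truth within the
threshold are *false positives*; truths without a matching detection are
*misdetections*. The three rates share a single denominator
(true + false positive + miss) so they always sum to 100 %.

Localization accuracy is root-mean-squared Euclidean error over matched
estimate/truth pairs, reported over the court plane ("XY") or full space
("XYZ").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .errors import UndefinedRateError
from .geometry import ImagePoint

#: Pixel threshold of the true-detection rule.
DEFAULT_MATCH_THRESHOLD_PX = 25.0


@dataclass
class MatchResult:
    """Counts and matched pairs of one detection-vs-truth comparison."""

    true_detections: int
    false_positives: int
    misdetections: int
    pairs: list[tuple[int, int, float]] = field(default_factory=list)
    # (detection index, truth index, pixel distance) for each match

    @property
    def pixel_distances(self) -> np.ndarray:
        return np.array([d for _, _, d in self.pairs])

    def __add__(self, other: "MatchResult") -> "MatchResult":
        return MatchResult(
            self.true_detections + other.true_detections,
            self.false_positives + other.false_positives,
            self.misdetections + other.misdetections,
            self.pairs + other.pairs,
        )


def _as_xy(points: Sequence[ImagePoint]) -> np.ndarray:
    if len(points) == 0:
        return np.zeros((0, 2))
    return np.array([[p.x, p.y] for p in points], dtype=float)


def match_detections(
    detected: Sequence[ImagePoint],
    truth: Sequence[ImagePoint],
    threshold_px: float = DEFAULT_MATCH_THRESHOLD_PX,
    optimal: bool = False,
) -> MatchResult:
    """Match detections to ground-truth heads under the pixel threshold.

    Greedy distance-sorted one-to-one matching by default (mirroring a
    manual-protocol comparison); ``optimal=True`` switches to Hungarian
    minimum-cost matching over the under-threshold pairs.
    """
    if threshold_px <= 0:
        raise ValueError("threshold_px must be positive")
    D = cdist(_as_xy(detected), _as_xy(truth)) if detected and truth else np.zeros((len(detected), len(truth)))
    pairs: list[tuple[int, int, float]] = []
    if D.size:
        if optimal:
            big = 10.0 * threshold_px
            cost = np.where(D <= threshold_px, D, big)
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if D[i, j] <= threshold_px:
                    pairs.append((int(i), int(j), float(D[i, j])))
        else:
            order = np.dstack(np.unravel_index(np.argsort(D, axis=None), D.shape))[0]
            used_det: set[int] = set()
            used_truth: set[int] = set()
            for i, j in order:
                if D[i, j] > threshold_px:
                    break
                if i in used_det or j in used_truth:
                    continue
                used_det.add(int(i))
                used_truth.add(int(j))
                pairs.append((int(i), int(j), float(D[i, j])))
    return MatchResult(
        true_detections=len(pairs),
        false_positives=len(detected) - len(pairs),
        misdetections=len(truth) - len(pairs),
        pairs=pairs,
    )


def detection_rates(result: MatchResult) -> tuple[float, float, float]:
    """(true %, false-positive %, misdetection %) on the shared denominator."""
    total = result.true_detections + result.false_positives + result.misdetections
    if total == 0:
        raise UndefinedRateError("no detections and no ground truth: rates undefined")
    return (
        100.0 * result.true_detections / total,
        100.0 * result.false_positives / total,
        100.0 * result.misdetections / total,
    )


def detection_pixel_rmse(result: MatchResult) -> float:
    """RMSE of the matched (true-detection) pixel distances."""
    d = result.pixel_distances
    if d.size == 0:
        raise UndefinedRateError("no matched detections: pixel RMSE undefined")
    return float(np.sqrt(np.mean(d**2)))


def localization_rmse(
    estimates: np.ndarray, truth: np.ndarray, axes: str = "xyz"
) -> float:
    """Root-mean-squared Euclidean error over matched position pairs.

    ``axes='xy'`` restricts the error to the court plane; ``'xyz'`` is the
    full spatial error. Inputs are (n, 3) arrays matched row-by-row.
    """
    est = np.atleast_2d(np.asarray(estimates, dtype=float))
    tru = np.atleast_2d(np.asarray(truth, dtype=float))
    if est.shape != tru.shape or est.shape[-1] != 3:
        raise ValueError(f"expected matched (n, 3) arrays, got {est.shape} vs {tru.shape}")
    if est.shape[0] == 0:
        raise UndefinedRateError("no matched pairs: RMSE undefined")
    cols = {"xy": (0, 1), "xyz": (0, 1, 2)}[axes.lower()]
    diff = est[:, cols] - tru[:, cols]
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
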