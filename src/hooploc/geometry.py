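"""Direct linear transformation (DLT) camera geometry.

A camera is an 11-parameter DLT model lambda_1..lambda_11 relating court-space
coordinates (X, Y, Z) in meters to image pixels (x, y)::

    x = (l1*X + l4*Y + l7*Z + l10) / (l3*X + l6*Y + l9*Z + 1)
    y = (l2*X + l5*Y + l8*Z + l11) / (l3*X + l6*Y + l9*Z + 1)

with the 12th projective parameter normalized to 1 (the "+1" in the shared
denominator). The world frame has its origin at the intersection of a lateral
line (X axis) and a bottom line (Y axis) of the court, Z up, in meters; image
coordinates are pixels, origin top-left, y downward.

Each world/image point pair contributes two linear equations in the eleven
unknowns, so calibration needs at least six pairs; both calibration and
triangulation are plain linear least-squares problems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    DegenerateGeometryError,
    DegenerateProjectionError,
    InsufficientCorrespondencesError,
    InsufficientViewsError,
)

#: Condition-number cap above which stacked linear systems are declared degenerate.
CONDITION_CAP = 1e10

#: Minimum |denominator| for a projection to be considered in front of the camera.
DENOMINATOR_EPS = 1e-9

#: Minimum number of world/image pairs for DLT calibration (11 unknowns, 2 eqs/pair).
MIN_CALIBRATION_PAIRS = 6

#: Number of DLT parameters per camera.
N_DLT_PARAMS = 11


@dataclass(frozen=True)
class WorldPoint:
    """A point in court space, meters."""

    X: float
    Y: float
    Z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.X, self.Y, self.Z], dtype=float)


@dataclass(frozen=True)
class ImagePoint:
    """A point in image space, pixels (origin top-left, y down)."""

    x: float
    y: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class Correspondence:
    """One calibration pair: a surveyed court point and its pixel observation."""

    world: WorldPoint
    image: ImagePoint
    camera_id: int = 0


@dataclass(frozen=True)
class CameraModel:
    """An 11-parameter DLT camera."""

    camera_id: int
    lambdas: tuple = field(default_factory=tuple)

    def __post_init__(self):
        lam = tuple(float(v) for v in self.lambdas)
        if len(lam) != N_DLT_PARAMS:
            raise ValueError(f"CameraModel needs exactly {N_DLT_PARAMS} parameters, got {len(lam)}")
        object.__setattr__(self, "lambdas", lam)

    @property
    def L(self) -> np.ndarray:
        return np.asarray(self.lambdas, dtype=float)

    def denominator(self, world: WorldPoint) -> float:
        l = self.L
        return l[2] * world.X + l[5] * world.Y + l[8] * world.Z + 1.0


def project(camera: CameraModel, point: WorldPoint) -> ImagePoint:
    """Project a court-space point into a camera's image plane.

    Raises
    ------
    DegenerateProjectionError
        If the projective denominator is within ``DENOMINATOR_EPS`` of zero
        (the point lies on or behind the camera's principal plane).
    """
    l = camera.L
    den = camera.denominator(point)
    if abs(den) < DENOMINATOR_EPS:
        raise DegenerateProjectionError(
            f"camera {camera.camera_id}: projection denominator {den:.3e} near zero"
        )
    x = (l[0] * point.X + l[3] * point.Y + l[6] * point.Z + l[9]) / den
    y = (l[1] * point.X + l[4] * point.Y + l[7] * point.Z + l[10]) / den
    return ImagePoint(x, y)


def reprojection_error(camera: CameraModel, world: WorldPoint, image: ImagePoint) -> float:
    """Squared re-projection error (x_p − x̂)² + (y_p − ŷ)², in px²."""
    proj = project(camera, world)
    return (proj.x - image.x) ** 2 + (proj.y - image.y) ** 2


def _check_condition(design: np.ndarray, context: str) -> None:
    s = np.linalg.svd(design, compute_uv=False)
    if s[-1] <= 0 or s[0] / s[-1] > CONDITION_CAP:
        raise DegenerateGeometryError(
            f"{context}: design matrix condition number exceeds {CONDITION_CAP:.0e}"
        )


def fit_dlt(correspondences: Sequence[Correspondence]) -> CameraModel:
    """Calibrate one camera from world/image point pairs by linear least squares.

    Each pair yields two equations in the eleven DLT parameters; at least six
    pairs (12 equations) are required. The design must be numerically full
    rank — all-coplanar or collinear calibration points are rejected.
    """
    corr = list(correspondences)
    if len(corr) < MIN_CALIBRATION_PAIRS:
        raise InsufficientCorrespondencesError(
            f"DLT calibration needs >= {MIN_CALIBRATION_PAIRS} point pairs "
            f"(11 unknowns, 2 equations per pair); got {len(corr)}"
        )
    cam_ids = {c.camera_id for c in corr}
    if len(cam_ids) != 1:
        raise ValueError(f"correspondences span multiple cameras: {sorted(cam_ids)}")
    (camera_id,) = cam_ids

    A = np.zeros((2 * len(corr), N_DLT_PARAMS))
    b = np.zeros(2 * len(corr))
    for i, c in enumerate(corr):
        X, Y, Z = c.world.X, c.world.Y, c.world.Z
        x, y = c.image.x, c.image.y
        A[2 * i] = [X, 0, -x * X, Y, 0, -x * Y, Z, 0, -x * Z, 1, 0]
        b[2 * i] = x
        A[2 * i + 1] = [0, X, -y * X, 0, Y, -y * Y, 0, Z, -y * Z, 0, 1]
        b[2 * i + 1] = y

    _check_condition(A, "DLT calibration")
    lam, *_ = np.linalg.lstsq(A, b, rcond=None)
    return CameraModel(camera_id=camera_id, lambdas=tuple(lam))


def triangulate(
    observations: Sequence[tuple[CameraModel, ImagePoint]],
) -> tuple[WorldPoint, np.ndarray]:
    """Recover a court-space point from >= 2 calibrated views.

    Stacks the two DLT equations of every observation into a 2q x 3 linear
    system in (X, Y, Z) and solves it in least squares.

    Returns the point and the per-observation Euclidean pixel re-projection
    errors, in the order the observations were given.
    """
    obs = list(observations)
    distinct = {cam.camera_id for cam, _ in obs}
    if len(distinct) < 2:
        raise InsufficientViewsError(
            f"triangulation needs observations from >= 2 distinct cameras, got {len(distinct)}"
        )

    A = np.zeros((2 * len(obs), 3))
    b = np.zeros(2 * len(obs))
    for i, (cam, pt) in enumerate(obs):
        l = cam.L
        x, y = pt.x, pt.y
        A[2 * i] = [l[0] - l[2] * x, l[3] - l[5] * x, l[6] - l[8] * x]
        b[2 * i] = x - l[9]
        A[2 * i + 1] = [l[1] - l[2] * y, l[4] - l[5] * y, l[7] - l[8] * y]
        b[2 * i + 1] = y - l[10]

    _check_condition(A, "triangulation")
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    world = WorldPoint(*sol)
    errors = np.array(
        [np.hypot(*(project(cam, world).as_array() - pt.as_array())) for cam, pt in obs]
    )
    return world, errors


def triangulate_fixed_height(
    observation: tuple[CameraModel, ImagePoint], Z: float
) -> WorldPoint:
    """Single-view localization with the height coordinate fixed a priori.

    Fixing Z in the two DLT equations of one observation leaves a 2x2 linear
    system in (X, Y). Used as the fallback for head points seen by only one
    camera, with Z set to the mean player head height.
    """
    cam, pt = observation
    l = cam.L
    x, y = pt.x, pt.y
    A = np.array(
        [
            [l[0] - l[2] * x, l[3] - l[5] * x],
            [l[1] - l[2] * y, l[4] - l[5] * y],
        ]
    )
    b = np.array(
        [
            x - l[9] - (l[6] - l[8] * x) * Z,
            y - l[10] - (l[7] - l[8] * y) * Z,
        ]
    )
    _check_condition(A, "fixed-height localization")
    X, Y = np.linalg.solve(A, b)
    return WorldPoint(X, Y, Z)


def camera_from_projection_matrix(P: np.ndarray, camera_id: int = 0) -> CameraModel:
    """Convert a 3x4 homogeneous projection matrix into DLT parameters.

    Requires P[2, 3] != 0 so the projective scale can be normalized to make
    the denominator constant equal 1.
    """
    P = np.asarray(P, dtype=float)
    if P.shape != (3, 4):
        raise ValueError(f"expected a 3x4 projection matrix, got {P.shape}")
    if abs(P[2, 3]) < DENOMINATOR_EPS:
        raise DegenerateGeometryError("projection matrix has P[2,3] ~ 0; cannot normalize")
    P = P / P[2, 3]
    lam = (
        P[0, 0], P[1, 0], P[2, 0],
        P[0, 1], P[1, 1], P[2, 1],
        P[0, 2], P[1, 2], P[2, 2],
        P[0, 3], P[1, 3],
    )
    return CameraModel(camera_id=camera_id, lambdas=lam)


def project_many(camera: CameraModel, points: Iterable[WorldPoint]) -> list[ImagePoint]:
    return [project(camera, p) for p in points]
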