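"""Synthetic multi-camera basketball scenes.

Generates everything the localization pipeline consumes, with known ground
truth: a rig of elevated DLT cameras framing one half court, player head
positions, noisy per-camera detections (Gaussian pixel noise, per-view
misses, uniform outlier clutter), and rendered grayscale image sequences
(textured static floor, body-plus-head player sprites, optional soft
shadows) for exercising the image-level detection stage.

The default geometry mirrors a typical acquisition: a 14 x 15 m half court
observed by three static cameras mounted ~12 m above the floor around the
court perimeter, producing nominal 1,038 x 776 px frames. Cameras are
synthesized directly as 11-parameter DLT vectors from a standard pinhole
composition (intrinsics times look-at extrinsics), so geometry tests do not
depend on the DLT fitter. Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .assignment import Detection, DetectionSet
from .errors import PackingError
from .geometry import CameraModel, ImagePoint, WorldPoint, camera_from_projection_matrix, project


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions for synthetic scenes.

    court_size
        Half-court extent (X, Y) in meters.
    n_players, n_cameras
        Players on court and static cameras in the rig.
    camera_height, camera_radius
        Mounting height above the floor and horizontal distance from the
        court center, meters.
    head_height_range
        Band from which player head heights are drawn (standing posture).
    min_separation
        Minimum pairwise court-plane distance between players, meters.
    noise_px
        Std of isotropic Gaussian pixel noise added to each detection.
    miss_prob
        Probability that a given (player, camera) view yields no detection.
    outliers_per_camera
        Non-head clutter points drawn uniformly over each frame.
    image_size
        Frame (width, height) in pixels.
    """

    court_size: tuple[float, float] = (14.0, 15.0)
    n_players: int = 3
    n_cameras: int = 3
    camera_height: float = 12.0
    camera_radius: float = 16.0
    head_height_range: tuple[float, float] = (1.65, 1.95)
    min_separation: Optional[float] = 2.0
    noise_px: float = 1.0
    miss_prob: float = 0.0
    outliers_per_camera: int = 0
    image_size: tuple[int, int] = (1038, 776)
    head_world_radius: float = 0.12
    shadows: bool = False
    image_noise: float = 0.0
    seed: int = 0


@dataclass
class SyntheticScene:
    """One generated frame: rig, ground truth, detections, and provenance.

    ``provenance[point_index]`` is ``("player", label)`` or ``("outlier", i)``.
    """

    cameras: list[CameraModel]
    truth: list[tuple[int, WorldPoint]]
    detections: DetectionSet
    provenance: dict[int, tuple[str, int]]
    config: SceneConfig


def _look_at_projection(
    center: np.ndarray, target: np.ndarray, focal: float, cx: float, cy: float
) -> np.ndarray:
    """3x4 pinhole projection matrix for a camera at `center` aimed at `target`."""
    forward = target - center
    forward = forward / np.linalg.norm(forward)
    up = np.array([0.0, 0.0, 1.0])
    right = np.cross(forward, up)
    right = right / np.linalg.norm(right)
    down = np.cross(forward, right)
    R = np.vstack([right, down, forward])
    K = np.array([[focal, 0.0, cx], [0.0, focal, cy], [0.0, 0.0, 1.0]])
    Rt = np.hstack([R, (-R @ center)[:, None]])
    return K @ Rt


def _court_envelope(config: SceneConfig) -> np.ndarray:
    """Extreme points every camera must keep in frame: court corners from the
    floor up to the jump apex."""
    cx, cy = config.court_size
    pts = []
    for X in (0.0, cx):
        for Y in (0.0, cy):
            for Z in (0.0, 3.2):
                pts.append((X, Y, Z))
    return np.array(pts)


def make_camera_rig(config: SceneConfig, seed: Optional[int] = None) -> list[CameraModel]:
    """Synthesize the DLT camera rig around the court perimeter.

    Cameras sit at ``camera_height`` on a circle of ``camera_radius`` around
    the court center (small seeded jitter in angle/radius/height), aimed at
    the center of the playing volume. The focal length of each camera is set
    so the whole court volume — corners at floor level up to jump apex —
    projects inside the frame with a safety margin.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    W, H = config.image_size
    court_cx, court_cy = config.court_size[0] / 2.0, config.court_size[1] / 2.0
    target = np.array([court_cx, court_cy, 1.5])
    envelope = _court_envelope(config)

    cameras = []
    for k in range(config.n_cameras):
        angle = 2.0 * math.pi * k / max(config.n_cameras, 1) + rng.uniform(-0.08, 0.08)
        radius = config.camera_radius + rng.uniform(-1.0, 1.0)
        height = config.camera_height + rng.uniform(-0.4, 0.4)
        center = np.array(
            [court_cx + radius * math.cos(angle), court_cy + radius * math.sin(angle), height]
        )
        # Normalized (f=1, principal point 0) coordinates of the envelope.
        P1 = _look_at_projection(center, target, 1.0, 0.0, 0.0)
        h = np.hstack([envelope, np.ones((len(envelope), 1))]) @ P1.T
        u, v = h[:, 0] / h[:, 2], h[:, 1] / h[:, 2]
        focal = 0.92 * min((W / 2.0) / np.abs(u).max(), (H / 2.0) / np.abs(v).max())
        P = _look_at_projection(center, target, focal, W / 2.0, H / 2.0)
        cameras.append(camera_from_projection_matrix(P, camera_id=k))
    return cameras


def sample_players(
    config: SceneConfig, seed: Optional[int] = None
) -> list[tuple[int, WorldPoint]]:
    """Draw player head positions uniformly over the court volume.

    X, Y uniform inside the court, head height Z uniform in
    ``head_height_range``; when ``min_separation`` is set, rejection sampling
    enforces the pairwise court-plane spacing.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cw, ch = config.court_size
    zlo, zhi = config.head_height_range
    players: list[tuple[int, WorldPoint]] = []
    for label in range(config.n_players):
        for _ in range(5000):
            X, Y = rng.uniform(0.5, cw - 0.5), rng.uniform(0.5, ch - 0.5)
            if config.min_separation is not None and any(
                math.hypot(X - p.X, Y - p.Y) < config.min_separation for _, p in players
            ):
                continue
            players.append((label, WorldPoint(X, Y, rng.uniform(zlo, zhi))))
            break
        else:
            raise PackingError(
                f"cannot place {config.n_players} players with "
                f"min separation {config.min_separation} m"
            )
    return players


def simulate_detections(
    truth: Sequence[tuple[int, WorldPoint]],
    cameras: Sequence[CameraModel],
    config: SceneConfig,
    seed: Optional[int] = None,
    frame_id: int = 0,
) -> tuple[DetectionSet, dict[int, tuple[str, int]]]:
    """Emulate the detection stage's per-camera output statistics.

    Each (player, camera) pair is observed with probability 1 − miss_prob;
    observed projections get isotropic Gaussian pixel noise of std noise_px.
    ``outliers_per_camera`` clutter points are appended uniformly over each
    frame. Projections falling outside the frame are dropped (counted as
    misses). Returns the detections plus a provenance map.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    W, H = config.image_size
    detections: list[Detection] = []
    provenance: dict[int, tuple[str, int]] = {}
    p = 0
    for cam in cameras:
        for label, world in truth:
            if config.miss_prob > 0 and rng.random() < config.miss_prob:
                continue
            img = project(cam, world)
            x = img.x + (rng.normal(0.0, config.noise_px) if config.noise_px > 0 else 0.0)
            y = img.y + (rng.normal(0.0, config.noise_px) if config.noise_px > 0 else 0.0)
            if not (0 <= x < W and 0 <= y < H):
                continue
            detections.append(Detection(p, cam.camera_id, ImagePoint(x, y)))
            provenance[p] = ("player", label)
            p += 1
        for i in range(config.outliers_per_camera):
            detections.append(
                Detection(p, cam.camera_id, ImagePoint(rng.uniform(0, W), rng.uniform(0, H)))
            )
            provenance[p] = ("outlier", i)
            p += 1
    return DetectionSet(frame_id, detections, list(cameras)), provenance


def make_scene(config: SceneConfig, seed: Optional[int] = None) -> SyntheticScene:
    """Convenience: rig + players + detections from one seed."""
    base = config.seed if seed is None else seed
    cameras = make_camera_rig(config, seed=base)
    truth = sample_players(config, seed=base + 1)
    detections, provenance = simulate_detections(truth, cameras, config, seed=base + 2)
    return SyntheticScene(cameras, truth, detections, provenance, config)


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------


@dataclass
class RenderedHead:
    """Ground truth for one rendered head in one camera frame."""

    label: int
    center: ImagePoint
    radius_px: float


@dataclass
class RenderedSequence:
    """Rendered frames of one camera plus per-frame ground truth."""

    camera_id: int
    frames: list[np.ndarray]  # uint8 (H, W)
    heads: list[list[RenderedHead]]
    masks: list[np.ndarray]  # bool (H, W), player pixels
    background: np.ndarray  # uint8 (H, W)


def make_trajectory(
    config: SceneConfig, n_frames: int, seed: Optional[int] = None
) -> list[list[tuple[int, WorldPoint]]]:
    """Linear constant-velocity walks for each player, bouncing off court walls."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    starts = sample_players(config, seed=(config.seed if seed is None else seed))
    cw, ch = config.court_size
    vel = rng.uniform(-0.06, 0.06, size=(len(starts), 2))  # m / frame
    frames: list[list[tuple[int, WorldPoint]]] = []
    pos = {label: np.array([p.X, p.Y]) for label, p in starts}
    z = {label: p.Z for label, p in starts}
    for _ in range(n_frames):
        snapshot = []
        for i, (label, _) in enumerate(starts):
            snapshot.append((label, WorldPoint(pos[label][0], pos[label][1], z[label])))
            pos[label] = pos[label] + vel[i]
            for axis, hi in ((0, cw), (1, ch)):
                if pos[label][axis] < 0.5 or pos[label][axis] > hi - 0.5:
                    vel[i, axis] = -vel[i, axis]
                    pos[label][axis] = np.clip(pos[label][axis], 0.5, hi - 0.5)
        frames.append(snapshot)
    return frames


def _pixel_scale(cam: CameraModel, world: WorldPoint, r_world: float) -> float:
    """Pixels per ``r_world`` meters at a world point, averaged over two axes."""
    c = project(cam, world).as_array()
    d = 0.0
    for off in ((r_world, 0.0, 0.0), (0.0, r_world, 0.0)):
        q = project(cam, WorldPoint(world.X + off[0], world.Y + off[1], world.Z + off[2]))
        d += np.linalg.norm(q.as_array() - c)
    return d / 2.0


def _make_background(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Mid-gray floor with smooth seeded texture, float in [0, 1]."""
    from scipy.ndimage import zoom

    H, W = shape
    coarse = rng.uniform(0.42, 0.60, size=(max(H // 24, 2), max(W // 24, 2)))
    tex = zoom(coarse, (H / coarse.shape[0], W / coarse.shape[1]), order=1)[:H, :W]
    return np.clip(tex, 0.0, 1.0)


def render_frames(
    trajectory: Sequence[Sequence[tuple[int, WorldPoint]]],
    cameras: Sequence[CameraModel],
    config: SceneConfig,
    seed: Optional[int] = None,
) -> list[RenderedSequence]:
    """Render grayscale image sequences for every camera.

    Players are drawn as a dark body ellipse (head-to-floor axis) topped by a
    bright circular head disk centered exactly on the projected head point,
    with projection-consistent radius. Optional soft shadows multiply the
    floor by 0.5 inside an offset ground ellipse. Per-frame ground truth
    (head centers, radii, player masks) is returned alongside the pixels.
    """
    base = config.seed if seed is None else seed
    W, H = config.image_size
    sequences = []
    for cam in cameras:
        rng = np.random.default_rng(base + 1000 * (cam.camera_id + 1))
        background = _make_background(rng, (H, W))
        body_shade = {
        }
        frames, heads_truth, masks = [], [], []
        for players in trajectory:
            img = background.copy()
            mask = np.zeros((H, W), dtype=bool)
            heads = []
            # shadows first, below every sprite
            if config.shadows:
                for label, head in players:
                    sc = WorldPoint(head.X + 0.55, head.Y + 0.35, 0.0)
                    try:
                        c = project(cam, sc)
                        s = _pixel_scale(cam, sc, 1.0)
                    except Exception:
                        continue
                    rr, cc = draw_ellipse(c.y, c.x, 0.45 * s, 0.85 * s, shape=(H, W))
                    img[rr, cc] = background[rr, cc] * 0.5
            for label, head in players:
                if label not in body_shade:
                    body_shade[label] = 0.08 + 0.10 * ((label * 7919) % 5) / 4.0
                hc = project(cam, head)
                r_px = _pixel_scale(cam, head, config.head_world_radius)
                feet = project(cam, WorldPoint(head.X, head.Y, 0.0))
                neck = hc.as_array() + 0.8 * r_px * _unit(feet.as_array() - hc.as_array())
                mid = (neck + feet.as_array()) / 2.0
                axis = feet.as_array() - neck
                half_len = np.linalg.norm(axis) / 2.0
                half_wid = max(_pixel_scale(cam, head, 0.20), 1.0)
                angle = math.atan2(axis[1], axis[0])
                rr, cc = draw_ellipse(
                    mid[1], mid[0], half_wid, max(half_len, 1.0),
                    rotation=-angle, shape=(H, W),
                )
                img[rr, cc] = body_shade[label]
                mask[rr, cc] = True
                rr, cc = draw_disk((hc.y, hc.x), max(r_px, 1.5), shape=(H, W))
                img[rr, cc] = 0.85
                mask[rr, cc] = True
                heads.append(RenderedHead(label, hc, r_px))
            if config.image_noise > 0:
                img = img + rng.normal(0.0, config.image_noise, size=img.shape)
            frames.append((np.clip(img, 0.0, 1.0) * 255).astype(np.uint8))
            heads_truth.append(heads)
            masks.append(mask)
        sequences.append(
            RenderedSequence(cam.camera_id, frames, heads_truth, masks,
                             (np.clip(background, 0, 1) * 255).astype(np.uint8))
        )
    return sequences


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def harvest_training_samples(
    sequences: Sequence[RenderedSequence],
    hog_config=None,
    negatives_per_frame: int = 3,
    seed: int = 0,
    hard_negatives: bool = True,
):
    """Labeled (hog, label) pairs from rendered ground truth.

    Positives are windows centered exactly on rendered heads. Negatives mix
    off-center heads (a head not centralized in the window counts as
    non-head), body crops, background crops, and — when ``hard_negatives``
    is on — actual circle-fitting candidates that landed far from any true
    head, the clutter the classifier must reject at detection time. Patches
    are taken from the foreground-masked grayscale, matching how candidate
    descriptors are computed during detection.
    """
    from .detection import HogConfig, HoughConfig, compute_hog, extract_head_candidates, extract_patch

    cfg = hog_config or HogConfig()
    rng = np.random.default_rng(seed)
    samples = []
    for seq in sequences:
        for frame, heads, mask in zip(seq.frames, seq.heads, seq.masks):
            gray = frame.astype(float) / 255.0 * mask
            H, W = gray.shape
            for head in heads:
                patch = extract_patch(gray, head.center, cfg.window)
                samples.append((compute_hog(patch, cfg), 1))
                # jittered copies: a head 1-2 px off center is still centered
                # at rasterization scale, and circle fitting is pixel-quantized
                for _ in range(2):
                    jit = ImagePoint(
                        head.center.x + rng.uniform(-2.0, 2.0),
                        head.center.y + rng.uniform(-2.0, 2.0),
                    )
                    samples.append((compute_hog(extract_patch(gray, jit, cfg.window), cfg), 1))
                # off-center heads: same object, not centralized -> negative;
                # offset direction uniform so body-top circles straight below
                # the head are represented among the negatives
                for _ in range(2):
                    angle = rng.uniform(0.0, 2.0 * np.pi)
                    dist = rng.uniform(2.0 * head.radius_px, 0.75 * cfg.window)
                    off = ImagePoint(
                        head.center.x + dist * np.cos(angle),
                        head.center.y + dist * np.sin(angle),
                    )
                    samples.append((compute_hog(extract_patch(gray, off, cfg.window), cfg), 0))
            for _ in range(negatives_per_frame):
                c = ImagePoint(rng.uniform(0, W), rng.uniform(0, H))
                samples.append((compute_hog(extract_patch(gray, c, cfg.window), cfg), 0))
            if hard_negatives:
                radii = [h.radius_px for h in heads]
                r_lo = max(int(min(radii, default=6) * 0.6), 3)
                r_hi = int(max(radii, default=12) * 1.8)
                cands = extract_head_candidates(
                    mask.astype(np.uint8), frame, None,
                    HoughConfig(r_min=r_lo, r_max=r_hi), cfg,
                )
                for cand in cands:
                    d = min(
                        (np.hypot(cand.center.x - h.center.x, cand.center.y - h.center.y)
                         for h in heads),
                        default=np.inf,
                    )
                    if d >= 10.0:
                        samples.append((cand.hog, 0))
    return samples


def full_frame_interest_area(config: SceneConfig, margin: float = 2.0) -> list[tuple[float, float]]:
    """Rectangular interest polygon covering the frame minus a small margin."""
    W, H = config.image_size
    return [(margin, margin), (W - margin, margin), (W - margin, H - margin), (margin, H - margin)]
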