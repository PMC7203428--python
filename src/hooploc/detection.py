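"""Per-camera head-candidate detection.

The image-level stage finds candidate player-head points in each camera
independently:

1. **Segmentation** — an adaptive per-pixel Gaussian-mixture background
   model separates moving players from the static court; pixels matching a
   darkened version of the background (cast shadows) are relabeled
   background.
2. **Cleaning** — morphological opening (erosion followed by dilation)
   removes speckle noise from the foreground mask.
3. **Head fitting** — player contours are traced on the mask; the topmost
   point of each contour and its interior local maxima seed a Circle Hough
   search for head-sized circles near each maximum (a contour may enclose
   several touching players, hence the local maxima).
4. **Classification** — a Histogram-of-Oriented-Gradients descriptor over a
   fixed square window around each candidate feeds a small feed-forward
   neural network (one hidden layer of 10 units) that separates heads from
   non-heads such as raised arms or the ball.

Candidates are only considered inside a per-camera interest-area polygon, so
spectators and off-court clutter never reach the classifier.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from shapely.geometry import Point as _ShapelyPoint
from shapely.geometry import Polygon as _ShapelyPolygon
from skimage.feature import canny, hog as _skimage_hog
from skimage.measure import find_contours
from skimage.morphology import footprint_rectangle, opening as _morph_opening
from skimage.transform import hough_circle, hough_circle_peaks
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier

from .assignment import Detection
from .errors import DegenerateTrainingError, InsufficientHistoryError
from .geometry import ImagePoint

# --------------------------------------------------------------------------
# Background segmentation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BackgroundConfig:
    """Adaptive Gaussian-mixture background model parameters.

    history sets the exponential learning rate (alpha = 1/history) and the
    default burn-in length; shadow_band is the intensity-ratio window
    (pixel / background) inside which a foreground pixel is relabeled as a
    cast shadow.
    """

    n_components: int = 3
    history: int = 120
    burn_in: Optional[int] = None  # defaults to history
    match_sigma: float = 2.5
    background_ratio: float = 0.7
    var_init: float = 15.0**2
    var_min: float = 4.0
    detect_shadows: bool = True
    shadow_band: tuple[float, float] = (0.35, 0.90)

    @property
    def effective_burn_in(self) -> int:
        return self.history if self.burn_in is None else self.burn_in


class GaussianMixtureBackground:
    """Per-pixel mixture-of-Gaussians background model (grayscale).

    Every pixel keeps K weighted Gaussians over intensity. A frame pixel is
    matched to the closest component within ``match_sigma`` standard
    deviations; matched components adapt toward the pixel, unmatched ones
    decay, and unmatched pixels replace the weakest component. Components
    are ranked by weight; the top components holding ``background_ratio`` of
    the total weight model the background, everything else is foreground.
    """

    def __init__(self, config: BackgroundConfig = BackgroundConfig()):
        self.config = config
        self._means: Optional[np.ndarray] = None  # (K, H, W)
        self._vars: Optional[np.ndarray] = None
        self._weights: Optional[np.ndarray] = None
        self.n_seen = 0

    def _init_model(self, frame: np.ndarray) -> None:
        K = self.config.n_components
        H, W = frame.shape
        self._means = np.tile(frame[None], (K, 1, 1)).astype(np.float32)
        # push spares away so they do not immediately shadow the first mode
        for k in range(1, K):
            self._means[k] += 80.0 * k / K
        self._vars = np.full((K, H, W), self.config.var_init, dtype=np.float32)
        self._weights = np.zeros((K, H, W), dtype=np.float32)
        self._weights[0] = 1.0

    def apply(self, frame: np.ndarray) -> np.ndarray:
        """Update the model with one grayscale frame; return the binary mask."""
        f = np.asarray(frame, dtype=np.float32)
        if f.ndim == 3:
            f = f.mean(axis=2)
        if self._means is None:
            self._init_model(f)
        cfg = self.config
        alpha = 1.0 / cfg.history
        means, var, w = self._means, self._vars, self._weights

        diff = f[None] - means
        dist2 = diff**2
        matched = dist2 <= (cfg.match_sigma**2) * var
        fitness = np.where(matched, w / np.sqrt(var), -np.inf)
        best = np.argmax(fitness, axis=0)  # (H, W)
        has_match = matched.any(axis=0)
        K = means.shape[0]
        own = (np.arange(K)[:, None, None] == best[None]) & has_match[None]

        w *= 1.0 - alpha
        w += alpha * own
        means += np.where(own, alpha * diff, 0.0)
        var += np.where(own, alpha * (dist2 - var), 0.0)
        np.maximum(var, cfg.var_min, out=var)

        # replace weakest component where nothing matched
        weakest = np.argmin(w, axis=0)
        repl = (np.arange(K)[:, None, None] == weakest[None]) & (~has_match[None])
        means[:] = np.where(repl, f[None], means)
        var[:] = np.where(repl, cfg.var_init, var)
        w[:] = np.where(repl, alpha, w)
        w /= w.sum(axis=0, keepdims=True)

        # background = top-ranked components up to background_ratio of weight
        order = np.argsort(-w, axis=0)
        w_sorted = np.take_along_axis(w, order, axis=0)
        cum = np.cumsum(w_sorted, axis=0)
        bg_sorted = (cum - w_sorted) < cfg.background_ratio
        is_bg = np.zeros_like(bg_sorted)
        np.put_along_axis(is_bg, order, bg_sorted, axis=0)

        matched_is_bg = np.take_along_axis(
            is_bg, best[None], axis=0
        )[0] & has_match
        fg = ~matched_is_bg

        if cfg.detect_shadows:
            bg_mean = np.take_along_axis(means, order[:1], axis=0)[0]
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(bg_mean > 1e-6, f / bg_mean, np.inf)
            lo, hi = cfg.shadow_band
            fg &= ~((ratio >= lo) & (ratio <= hi))

        self.n_seen += 1
        return fg.astype(np.uint8)

    @property
    def background_image(self) -> np.ndarray:
        """Dominant-component mean intensity per pixel."""
        if self._means is None:
            raise InsufficientHistoryError("background model has seen no frames")
        top = np.argmax(self._weights, axis=0)
        return np.take_along_axis(self._means, top[None], axis=0)[0]


def segment_foreground(
    frames: Sequence[np.ndarray], config: BackgroundConfig = BackgroundConfig()
) -> list[np.ndarray]:
    """Segment a frame stream; returns one binary mask per post-burn-in frame.

    The first ``burn_in`` frames (default: the model history length) only
    train the background model; masks are emitted for every later frame.
    """
    frames = list(frames)
    burn = config.effective_burn_in
    if len(frames) < burn:
        raise InsufficientHistoryError(
            f"need >= {burn} frames to form the background model, got {len(frames)}"
        )
    model = GaussianMixtureBackground(config)
    masks = []
    for i, frame in enumerate(frames):
        mask = model.apply(frame)
        if i >= burn:
            masks.append(mask)
    return masks


def clean_mask(mask: np.ndarray, kernel_size: int = 3) -> np.ndarray:
    """Morphological opening (erosion followed by dilation) of a binary mask."""
    footprint = footprint_rectangle((kernel_size, kernel_size))
    return _morph_opening(mask.astype(bool), footprint).astype(np.uint8)


# --------------------------------------------------------------------------
# Head candidates: contours, local maxima, Circle Hough
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class InterestArea:
    """Per-camera polygon restricting detection to the court region."""

    camera_id: int
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self):
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        if len(verts) < 3:
            raise ValueError("interest area needs at least 3 vertices")
        poly = _ShapelyPolygon(verts)
        if not poly.is_valid:
            raise ValueError("interest area polygon must be simple (non-self-intersecting)")
        object.__setattr__(self, "vertices", verts)

    @property
    def polygon(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)

    def contains(self, point: ImagePoint) -> bool:
        return self.polygon.covers(_ShapelyPoint(point.x, point.y))


@dataclass(frozen=True)
class HoughConfig:
    """Circle-Hough head-fitting parameters (pixels)."""

    r_min: int = 6
    r_max: int = 20
    center_max_dist: Optional[float] = None  # defaults to 1.5 * r_max
    nms_px: float = 5.0
    min_contour_points: int = 20
    canny_sigma: float = 1.6
    accumulator_threshold: float = 0.30

    @property
    def effective_center_max_dist(self) -> float:
        return 1.5 * self.r_max if self.center_max_dist is None else self.center_max_dist


@dataclass
class HeadCandidate:
    """A head-sized circle near a contour maximum, ready for classification."""

    center: ImagePoint
    radius: float
    source_maximum: ImagePoint
    hog: np.ndarray
    accumulator: float
    probability: Optional[float] = None


def contour_local_maxima(contour: np.ndarray, nms_px: float = 5.0, window: int = 5) -> list[tuple[float, float]]:
    """Topmost points of a closed contour: local minima of the image row
    coordinate (y grows downward), with Euclidean non-maximum suppression.

    `contour` is an (N, 2) array of (row, col) as produced by
    ``skimage.measure.find_contours``. Returns (x, y) pixel tuples, best
    (topmost) first.
    """
    rows = contour[:, 0]
    n = len(rows)
    if n == 0:
        return []
    idx = np.arange(n)
    is_min = np.ones(n, dtype=bool)
    for step in range(1, window + 1):
        is_min &= rows <= rows[(idx + step) % n]
        is_min &= rows <= rows[(idx - step) % n]
    cand = sorted(idx[is_min], key=lambda i: (rows[i], contour[i, 1]))
    kept: list[tuple[float, float]] = []
    for i in cand:
        x, y = contour[i, 1], contour[i, 0]
        if all((x - kx) ** 2 + (y - ky) ** 2 >= nms_px**2 for kx, ky in kept):
            kept.append((x, y))
    return kept


def _best_circle_near(
    gray_fg: np.ndarray,
    maximum: tuple[float, float],
    config: HoughConfig,
) -> Optional[tuple[float, float, float, float]]:
    """Best Hough circle near one contour maximum: (cx, cy, r, accumulator)."""
    H, W = gray_fg.shape
    mx, my = maximum
    reach = int(np.ceil(config.effective_center_max_dist + config.r_max)) + 2
    r0, r1 = max(int(my) - reach, 0), min(int(my) + reach + 1, H)
    c0, c1 = max(int(mx) - reach, 0), min(int(mx) + reach + 1, W)
    window = gray_fg[r0:r1, c0:c1]
    if window.size == 0:
        return None
    edges = canny(window, sigma=config.canny_sigma)
    if not edges.any():
        return None
    radii = np.arange(config.r_min, config.r_max + 1)
    accum = hough_circle(edges, radii)
    peaks = hough_circle_peaks(accum, radii, total_num_peaks=5)
    best = None
    for acc, cx, cy, r in zip(*peaks):
        if acc < config.accumulator_threshold:
            continue
        gx, gy = cx + c0, cy + r0
        if (gx - mx) ** 2 + (gy - my) ** 2 > config.effective_center_max_dist**2:
            continue
        if best is None or acc > best[3]:
            best = (float(gx), float(gy), float(r), float(acc))
    return best


def extract_head_candidates(
    mask: np.ndarray,
    grayscale_frame: np.ndarray,
    interest_area: Optional[InterestArea],
    hough_config: HoughConfig = HoughConfig(),
    hog_config: Optional["HogConfig"] = None,
) -> list[HeadCandidate]:
    """Head-sized circles near the top of every foreground contour.

    Contours of the cleaned mask are traced; the topmost point of each
    contour plus its interior local maxima (one per touching player) seed a
    local Circle Hough search on the grayscale foreground. Circles too far
    from their seed, weak accumulator peaks, duplicates, and centers outside
    the interest area are discarded. Each surviving candidate carries its
    HOG descriptor computed on the raw grayscale frame.
    """
    hog_config = hog_config or HogConfig()
    gray = np.asarray(grayscale_frame, dtype=float)
    if gray.ndim == 3:
        gray = gray.mean(axis=2)
    if gray.max() > 1.0:
        gray = gray / 255.0
    gray_fg = gray * (mask > 0)

    candidates: list[HeadCandidate] = []
    for contour in find_contours(mask.astype(float), 0.5):
        if len(contour) < hough_config.min_contour_points:
            continue
        for maximum in contour_local_maxima(contour, nms_px=hough_config.nms_px):
            hit = _best_circle_near(gray_fg, maximum, hough_config)
            if hit is None:
                continue
            gx, gy, r, acc = hit
            center = ImagePoint(gx, gy)
            if interest_area is not None and not interest_area.contains(center):
                continue
            dup = next(
                (
                    c
                    for c in candidates
                    if (c.center.x - gx) ** 2 + (c.center.y - gy) ** 2 < hough_config.r_min**2
                ),
                None,
            )
            if dup is not None:
                if acc > dup.accumulator:
                    candidates.remove(dup)
                else:
                    continue
            # HOG on the foreground-masked grayscale: the descriptor encodes
            # the player's shape, not the incidental background texture that
            # block normalization would otherwise amplify
            patch = extract_patch(gray_fg, center, hog_config.window)
            candidates.append(
                HeadCandidate(
                    center=center,
                    radius=r,
                    source_maximum=ImagePoint(*maximum),
                    hog=compute_hog(patch, hog_config),
                    accumulator=acc,
                )
            )
    candidates.sort(key=lambda c: (-c.accumulator, c.center.x, c.center.y))
    return candidates


# --------------------------------------------------------------------------
# HOG features
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class HogConfig:
    """Dalal-Triggs HOG geometry; the default yields a 1,764-long descriptor
    (64x64 window, 8x8-px cells, 2x2-cell blocks, one-cell stride, 9 bins)."""

    window: int = 64
    cell: int = 8
    block: int = 2
    orientations: int = 9

    @property
    def length(self) -> int:
        cells = self.window // self.cell
        blocks = cells - self.block + 1
        return blocks**2 * self.block**2 * self.orientations


def hog_length(config: HogConfig = HogConfig()) -> int:
    """Closed-form descriptor length for a HOG configuration."""
    return config.length


def compute_hog(patch: np.ndarray, config: HogConfig = HogConfig()) -> np.ndarray:
    """HOG descriptor of one square grayscale patch.

    The patch must be ``window`` x ``window``; entries are non-negative and a
    constant patch yields an all-zero descriptor (zero gradients with guarded
    block normalization).
    """
    patch = np.asarray(patch, dtype=float)
    if patch.shape != (config.window, config.window):
        raise ValueError(f"expected a {config.window}x{config.window} patch, got {patch.shape}")
    return _skimage_hog(
        patch,
        orientations=config.orientations,
        pixels_per_cell=(config.cell, config.cell),
        cells_per_block=(config.block, config.block),
        block_norm="L2-Hys",
        feature_vector=True,
    )


def extract_patch(gray: np.ndarray, center: ImagePoint, window: int) -> np.ndarray:
    """Square patch centered on a candidate, replicate-padded at the border."""
    half = window // 2
    r, c = int(round(center.y)), int(round(center.x))
    H, W = gray.shape
    pad = max(0, half - r, half - c, r + half - H, c + half - W) + 1
    padded = np.pad(gray, pad, mode="edge")
    r += pad
    c += pad
    return padded[r - half : r - half + window, c - half : c - half + window]


# --------------------------------------------------------------------------
# Head / non-head classifier
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassifierSpec:
    """Feed-forward head classifier: HOG input, one hidden layer of 10 units,
    logistic activations, 70/15/15 train/validation/test split, early
    stopping on the validation split."""

    input_size: int = 1764
    hidden_layers: tuple[int, ...] = (10,)
    splits: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    max_epochs: int = 300
    patience: int = 20
    learning_rate_init: float = 2e-3

    def __post_init__(self):
        if abs(sum(self.splits) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class SplitMetrics:
    accuracy: float
    confusion: np.ndarray  # 2x2, rows true / cols predicted, head = 1


@dataclass
class TrainedHeadClassifier:
    """Trained MLP plus per-split performance; head probability via
    ``predict_proba``."""

    model: MLPClassifier
    spec: ClassifierSpec
    metrics: dict[str, SplitMetrics]
    n_epochs: int

    def predict_proba(self, hogs: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(hogs, dtype=float))
        head_col = list(self.model.classes_).index(1)
        return self.model.predict_proba(X)[:, head_col]


_LABEL_MAP = {0: 0, 1: 1, "non-head": 0, "head": 1, False: 0, True: 1}


def train_head_classifier(
    samples: Iterable[tuple[np.ndarray, object]], spec: ClassifierSpec = ClassifierSpec()
) -> TrainedHeadClassifier:
    """Train the head/non-head network with early stopping.

    Samples are (hog, label) pairs, labels ``head``/``non-head`` (or 1/0).
    Data is split 70/15/15 (stratified, seeded); training runs full epochs
    of back-propagation and stops once the validation cross-entropy has not
    improved for ``patience`` epochs, restoring the best weights. Returns
    the classifier with confusion matrices and accuracies for all three
    splits.
    """
    pairs = list(samples)
    X = np.array([np.asarray(h, dtype=float) for h, _ in pairs])
    y = np.array([_LABEL_MAP[lab] for _, lab in pairs])
    if len(np.unique(y)) < 2:
        raise DegenerateTrainingError("training requires both head and non-head samples")

    f_train, f_val, f_test = spec.splits
    X_train, X_rest, y_train, y_rest = train_test_split(
        X, y, train_size=f_train, random_state=spec.seed, stratify=y
    )
    X_val, X_test, y_val, y_test = train_test_split(
        X_rest, y_rest, train_size=f_val / (f_val + f_test),
        random_state=spec.seed, stratify=y_rest,
    )

    clf = MLPClassifier(
        hidden_layer_sizes=spec.hidden_layers,
        activation="logistic",
        solver="adam",
        learning_rate_init=spec.learning_rate_init,
        random_state=spec.seed,
    )
    best_loss, best_state, since_best, epoch = np.inf, None, 0, 0
    for epoch in range(1, spec.max_epochs + 1):
        clf.partial_fit(X_train, y_train, classes=np.array([0, 1]))
        p = np.clip(clf.predict_proba(X_val)[:, 1], 1e-12, 1 - 1e-12)
        val_loss = float(-np.mean(y_val * np.log(p) + (1 - y_val) * np.log(1 - p)))
        if val_loss < best_loss - 1e-5:
            best_loss = val_loss
            best_state = (copy.deepcopy(clf.coefs_), copy.deepcopy(clf.intercepts_))
            since_best = 0
        else:
            since_best += 1
            if since_best >= spec.patience:
                break
    if best_state is not None:
        clf.coefs_, clf.intercepts_ = best_state

    metrics = {}
    for name, Xs, ys in (
        ("train", X_train, y_train),
        ("validation", X_val, y_val),
        ("test", X_test, y_test),
    ):
        pred = clf.predict(Xs)
        metrics[name] = SplitMetrics(
            accuracy=float((pred == ys).mean()),
            confusion=confusion_matrix(ys, pred, labels=[0, 1]),
        )
    return TrainedHeadClassifier(model=clf, spec=spec, metrics=metrics, n_epochs=epoch)


def classify_candidates(
    candidates: Sequence[HeadCandidate],
    classifier: Optional[TrainedHeadClassifier],
    threshold: float = 0.5,
    camera_id: int = 0,
    start_index: int = 0,
) -> list[Detection]:
    """Turn candidates whose head probability clears the threshold into
    detections; without a classifier every candidate passes (probability 1)."""
    detections: list[Detection] = []
    if candidates and classifier is not None:
        probs = classifier.predict_proba(np.array([c.hog for c in candidates]))
    else:
        probs = np.ones(len(candidates))
    p = start_index
    for cand, prob in zip(candidates, probs):
        cand.probability = float(prob)
        if prob >= threshold:
            detections.append(Detection(p, camera_id, cand.center, score=float(prob)))
            p += 1
    return detections


# --------------------------------------------------------------------------
# Full per-camera pipeline
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DetectionConfig:
    """Bundle of every image-stage parameter for one run."""

    background: BackgroundConfig = BackgroundConfig()
    hough: HoughConfig = HoughConfig()
    hog: HogConfig = HogConfig()
    clean_kernel: int = 3
    threshold: float = 0.5


def detect_heads(
    frames: Sequence[np.ndarray],
    interest_area: Optional[InterestArea],
    config: DetectionConfig = DetectionConfig(),
    classifier: Optional[TrainedHeadClassifier] = None,
    camera_id: int = 0,
) -> list[list[Detection]]:
    """Run the whole image stage on one camera's frame sequence.

    The first ``burn_in`` frames train the background model; every later
    frame yields a (possibly empty) detection list. Point indices restart at
    zero each frame.
    """
    masks = segment_foreground(frames, config.background)
    burn = config.background.effective_burn_in
    out: list[list[Detection]] = []
    for mask, frame in zip(masks, list(frames)[burn:]):
        cleaned = clean_mask(mask, config.clean_kernel)
        candidates = extract_head_candidates(
            cleaned, frame, interest_area, config.hough, config.hog
        )
        out.append(
            classify_candidates(candidates, classifier, config.threshold, camera_id=camera_id)
        )
    return out
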