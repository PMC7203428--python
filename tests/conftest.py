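"""Shared fixtures: toy cameras, synthetic rigs, and rendered sequences.

Rendering and classifier training are session-scoped because several test
modules (and the acceptance suite) share them; everything is seeded.
"""

from __future__ import annotations

import numpy as np
import pytest

from hooploc.assignment import OptimizationConfig
from hooploc.detection import (
    BackgroundConfig,
    ClassifierSpec,
    DetectionConfig,
    HoughConfig,
    InterestArea,
    detect_heads,
    train_head_classifier,
)
from hooploc.geometry import CameraModel
from hooploc.synthetic import (
    SceneConfig,
    full_frame_interest_area,
    harvest_training_samples,
    make_camera_rig,
    make_trajectory,
    render_frames,
)

# Identity-like test cameras: affine maps with unit denominator.
AFFINE_XY = CameraModel(camera_id=0, lambdas=(1, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0))  # x=X, y=Y
AFFINE_XZ = CameraModel(camera_id=1, lambdas=(1, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0))  # x=X, y=Z
AFFINE_YZ = CameraModel(camera_id=2, lambdas=(0, 0, 0, 1, 0, 0, 0, 1, 0, 0, 0))  # x=Y, y=Z


@pytest.fixture
def affine_camera() -> CameraModel:
    return AFFINE_XY


@pytest.fixture(scope="session")
def default_config() -> OptimizationConfig:
    return OptimizationConfig()


@pytest.fixture(scope="session")
def rig3() -> list[CameraModel]:
    """Default 3-camera rig over the full half court."""
    return make_camera_rig(SceneConfig(seed=0), seed=0)


# ---------------------------------------------------------------- rendering

#: Zoomed scene used for image-level tests: the cameras frame a 7 x 7.5 m
#: region so rendered heads are ~6 px — comparable, relative to frame size,
#: to heads in nominal-resolution footage.
RENDER_CONFIG = SceneConfig(
    n_players=3,
    n_cameras=1,
    court_size=(7.0, 7.5),
    camera_radius=10.0,
    image_size=(520, 388),
    head_world_radius=0.16,
    min_separation=1.5,
    seed=5,
)

RENDER_BURN_IN = 40


@pytest.fixture(scope="session")
def render_config() -> SceneConfig:
    return RENDER_CONFIG


@pytest.fixture(scope="session")
def render_rig(render_config) -> list[CameraModel]:
    return make_camera_rig(render_config, seed=5)


@pytest.fixture(scope="session")
def detection_config() -> DetectionConfig:
    return DetectionConfig(
        background=BackgroundConfig(history=RENDER_BURN_IN),
        hough=HoughConfig(r_min=4, r_max=12),
    )


@pytest.fixture(scope="session")
def head_classifier(render_config, render_rig):
    """MLP trained on HOG patches harvested from a rendered training sequence."""
    trajectory = make_trajectory(render_config, 30, seed=11) + make_trajectory(
        render_config, 30, seed=14
    )
    sequences = render_frames(trajectory, render_rig, render_config, seed=12)
    samples = harvest_training_samples(sequences, negatives_per_frame=3, seed=13)
    return train_head_classifier(samples, ClassifierSpec(seed=0, max_epochs=150))


@pytest.fixture(scope="session")
def eval_sequence(render_config, render_rig):
    """Burn-in background frames followed by three players walking."""
    trajectory = [[] for _ in range(RENDER_BURN_IN)] + make_trajectory(render_config, 18, seed=6)
    (sequence,) = render_frames(trajectory, render_rig, render_config, seed=7)
    return sequence


@pytest.fixture(scope="session")
def eval_interest_area(render_config) -> InterestArea:
    return InterestArea(0, tuple(full_frame_interest_area(render_config)))


@pytest.fixture(scope="session")
def eval_detections(eval_sequence, eval_interest_area, detection_config, head_classifier):
    """End-to-end detections on the evaluation sequence (post burn-in)."""
    return detect_heads(
        eval_sequence.frames, eval_interest_area, detection_config, head_classifier, camera_id=0
    )
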