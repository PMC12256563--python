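"""Shared fixtures: the default phantom model and reusable synthetic renders."""

import numpy as np
import pytest

from helixreg import (
    PhantomGeometry,
    RenderConfig,
    ThresholdSpec,
    generate_model,
    render_phantom_cbct,
)
from helixreg.transforms import HomogeneousTransform, identity


@pytest.fixture(scope="session")
def geometry() -> PhantomGeometry:
    return PhantomGeometry()


@pytest.fixture(scope="session")
def model(geometry):
    return generate_model(geometry)


@pytest.fixture(scope="session")
def model_large(model):
    return sorted((f for f in model if f.size_class == "large"), key=lambda f: f.index)


def random_rigid(rng: np.random.Generator, frame_from="p", frame_to="c",
                 max_angle_deg: float = 180.0, max_translation: float = 20.0) -> HomogeneousTransform:
    """Uniform-ish random rigid transform for property tests."""
    from scipy.spatial.transform import Rotation

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(-max_angle_deg, max_angle_deg)
    m = np.eye(4)
    m[:3, :3] = Rotation.from_rotvec(np.radians(angle) * axis).as_matrix()
    m[:3, 3] = rng.uniform(-max_translation, max_translation, size=3)
    return HomogeneousTransform(m, frame_from, frame_to)


def rotation_angle_deg(r1: np.ndarray, r2: np.ndarray) -> float:
    """Geodesic angle between two rotation matrices."""
    cos = (np.trace(r1.T @ r2) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


@pytest.fixture(scope="session")
def centered_noise_free_render(model):
    """Noise-free 0.5 mm render of the centered phantom plus its ground truth."""
    cfg = RenderConfig(voxel_size=0.5, noise_sigma=0.0, seed=0)
    return render_phantom_cbct(model, identity("p", "c"), cfg)


@pytest.fixture(scope="session")
def expected_volume_spec():
    return ThresholdSpec(mode="expected-volume")
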