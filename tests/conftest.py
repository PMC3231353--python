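import numpy as np
import pytest

from teashoot3d.features import extract_shoot_features
from teashoot3d.synthetic_data import FixtureSpec, LeafSpec, render_fixture, table1_spec


@pytest.fixture(scope="session")
def table1_fixture():
    """The reference shoot rendered once per session."""
    return render_fixture(table1_spec())


@pytest.fixture(scope="session")
def table1_features(table1_fixture):
    return extract_shoot_features(table1_fixture.organ_masks)


@pytest.fixture(scope="session")
def tiny_spec():
    """A small-canvas spec for tests that segment noisy images."""
    return FixtureSpec(
        rng_seed=5,
        branch_length=60.0,
        branch_diameter=10.0,
        bud_length=40.0,
        bud_diameter=12.0,
        bud_angle_deg=70.0,
        margin=8,
        leaves=(
            LeafSpec(order=1, length=60.0, width=24.0, theta_deg=55.0, side=1),
            LeafSpec(order=2, length=70.0, width=28.0, theta_deg=115.0, side=-1),
        ),
        n_background_blobs=2,
    )


def iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return inter / union if union else 1.0
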