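import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from epiflex.core import ConformationFrame, ResidueLabel, TrajectoryEnsemble

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_labels(n, start=1, chain="A", icodes=None):
    icodes = icodes or {}
    labels = []
    for k in range(n):
        num = start + k
        labels.append(
            ResidueLabel(chain_id=chain, crystal_number=num,
                         insertion_code=icodes.get(num, ""), residue_name="GLY")
        )
    return tuple(labels)


def make_frame(coords, start=1):
    coords = np.asarray(coords, dtype=float)
    return ConformationFrame(make_labels(coords.shape[0], start=start), coords)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_frame():
    """A 5-residue non-degenerate toy conformation."""
    coords = np.array(
        [[0.0, 0.0, 0.0], [3.8, 0.0, 0.0], [5.0, 3.1, 0.5],
         [2.2, 5.6, 1.9], [-1.0, 4.0, 3.0]]
    )
    return make_frame(coords)


@pytest.fixture
def random_rigid(rng):
    """Factory for a random proper rotation + translation."""
    from scipy.spatial.transform import Rotation

    def _make():
        rot = Rotation.random(rng=rng).as_matrix()
        trans = rng.uniform(-15, 15, size=3)
        return rot, trans

    return _make


def apply_rigid(coords, rot, trans):
    return np.asarray(coords) @ rot.T + trans


@pytest.fixture
def small_ensemble(rng):
    """3 replicas x 12 frames of a 8-residue chain with mild noise."""
    base = np.cumsum(rng.normal(scale=2.0, size=(8, 3)), axis=0)
    reps = [base + rng.normal(scale=0.3, size=(12, 8, 3)) for _ in range(3)]
    return TrajectoryEnsemble(make_labels(8), reps)
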