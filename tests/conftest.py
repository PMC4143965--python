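import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import synapstat as ss
from synapstat.reference import sample_table

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cube():
    return ss.Box3D([1000.0, 1000.0, 1000.0])


@pytest.fixture(scope="session")
def default_study():
    """One synthetic study shared across read-only tests."""
    return ss.generate_study(seed=314)


@pytest.fixture(scope="session")
def table_study():
    """A study whose per-sample counts and window volumes equal the
    published per-sample table exactly (point locations are arbitrary)."""
    rng = np.random.default_rng(7)
    patterns = []
    for row in sample_table().itertuples():
        side = (row.volume_um3 * 1e9) ** (1.0 / 3.0)
        box = ss.Box3D([side, side, side])
        coords = rng.random((row.n_synapses, 3)) * box.side_lengths
        patterns.append(
            ss.PointPattern3D(
                box=box,
                coords=coords,
                layer=row.layer,
                animal=row.animal,
                sample_id=row.sample,
            )
        )
    return ss.StudyCollection(patterns)


def random_pattern(rng, n, sides=(1000.0, 800.0, 600.0)):
    box = ss.Box3D(list(sides))
    return ss.PointPattern3D(box=box, coords=rng.random((n, 3)) * box.side_lengths)
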