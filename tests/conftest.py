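import numpy as np
import pytest

import structatlas as sa


@pytest.fixture
def geom64():
    return sa.VolumeGeometry((64, 64, 64), (1.0, 1.0, 1.0))


@pytest.fixture
def ribbon(geom64):
    """Flat 20 x 10 x 1 mm ribbon fold (exactly 200 voxels at 1 mm iso)."""
    curve = np.array([[20.0, 30.0, 50.0], [40.0, 30.0, 50.0]])
    return sa.generate_fold(curve, 10.0, geometry=geom64)


def small_config(seed=0, n_subjects=1, n_labels=6, **profile_kwargs):
    profile = sa.VariabilityProfile(**profile_kwargs) if profile_kwargs else sa.VariabilityProfile()
    return sa.GeneratorConfig(
        seed=seed,
        n_subjects=n_subjects,
        label_set=sa.default_nomenclature(n_labels),
        variability=profile,
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """Five-subject cohort with six labels, shared by read-only tests."""
    config = sa.GeneratorConfig(
        seed=7, n_subjects=5, label_set=sa.default_nomenclature(6)
    )
    return sa.generate_cohort(config)
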