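import numpy as np
import pytest

from ctta.synthetic import PhantomSpec, generate_cohort


def small_phantom_spec(seed: int = 7, **overrides) -> PhantomSpec:
    """A fast 3+3-subject cohort used by several suites."""
    params = dict(
        n_low=3,
        n_high=3,
        volume_shape=(48, 48, 16),
        lesion_radius_range=(12.0, 16.0),
        seed=seed,
    )
    params.update(overrides)
    return PhantomSpec(**params)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """(spec, manifest) for a generated 3+3 cohort; treat as read-only."""
    out = tmp_path_factory.mktemp("small_cohort")
    spec = small_phantom_spec()
    manifest = generate_cohort(spec, out)
    return spec, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
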