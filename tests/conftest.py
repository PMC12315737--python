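import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mebold as mb

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

TABLE_TES = np.array(mb.DEFAULT_TE_MS)


@pytest.fixture(scope="session")
def table_tes():
    return TABLE_TES.copy()


def small_rois():
    """Scaled-down versions of the default regions for a 12x12x6 grid."""
    return (
        mb.ROIDef("ofc", (1, 5, 1, 5, 1, 5), s0=800.0, t2star_ms=18.0, bold_effect=0.02),
        mb.ROIDef("piriform", (7, 11, 1, 5, 1, 5), s0=900.0, t2star_ms=30.0,
                  bold_effect=0.02),
        mb.ROIDef("cortex", (1, 5, 7, 11, 1, 5), s0=1000.0, t2star_ms=45.0,
                  bold_effect=0.02),
        mb.ROIDef("white", (7, 11, 7, 11, 1, 5), s0=950.0, t2star_ms=40.0,
                  bold_effect=0.0, conditions=()),
    )


def small_spec(seed=7, **overrides):
    """A reduced phantom keeping the acquisition's temporal structure."""
    kwargs = dict(
        seed=seed,
        grid_shape=(12, 12, 6),
        n_volumes=100,
        rois=small_rois(),
    )
    kwargs.update(overrides)
    return mb.PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def small_phantom():
    return mb.generate_phantom(small_spec())
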