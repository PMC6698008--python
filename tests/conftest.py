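import numpy as np
import pytest

from mvdquant import SlideSpec, generate_slide


@pytest.fixture(scope="session")
def small_slide():
    """A 600x600 synthetic slide at 5% target positive fraction."""
    spec = SlideSpec(
        width_px=600,
        height_px=600,
        target_positive_fraction=0.05,
        vessel_count=15,
        vessel_size_range_px=(100, 1500),
        seed=42,
    )
    return generate_slide(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
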