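import numpy as np
import pytest

import inclusiontools as it


@pytest.fixture
def noiseless_scene():
    """Uniform cerulean disk + shell TMR + coat antibody, no noise."""
    spec = it.SceneSpec(
        channel_profiles={
            "cerulean": it.uniform(200.0),
            "tmr": it.shell(10.0, 100.0, 0.9),
            "antibody": it.coat(0.0, 200.0, 5.0),
        },
        noise_sigma=0.0,
        seed=0,
    )
    return it.render_scene(spec)


@pytest.fixture
def disk_roi():
    """A radius-20 disk ROI centred in a 200x200 image."""
    from oracle_utils import raster_disk

    return it.PixelROI.from_mask(raster_disk((200, 200), (100, 100), 20))


@pytest.fixture
def small_population():
    return it.simulate_population(it.PopulationSpec(n_events=5000, seed=11))


@pytest.fixture
def gate_calibration():
    negative = it.simulate_population(
        it.PopulationSpec(n_events=2000, logistic_intercept=-30.0, seed=21))
    positive = it.simulate_population(
        it.PopulationSpec(n_events=2000, logistic_intercept=30.0, seed=22))
    return {"negative": negative, "positive": positive}
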