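import numpy as np
import pytest
from hypothesis import settings

import cyanocycle as cc

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")

#: continuous-light noise summaries used throughout: birth-volume CV 0.12,
#: growth-rate CV 0.30, sister birth-size asymmetry SD 0.033
NOISE = dict(target_birth_cv=0.12, growth_rate_cv=0.30, asym_sd=0.033)


@pytest.fixture(scope="session")
def calibrated_adder():
    return cc.calibrate_noise("adder", seed=1, **NOISE)


@pytest.fixture(scope="session")
def calibrated_specs(calibrated_adder):
    return {
        "adder": calibrated_adder,
        "sizer": cc.calibrate_noise("sizer", seed=1, **NOISE),
        "timer": cc.calibrate_noise("timer", seed=1, on_unreachable="floor",
                                    **NOISE),
    }


@pytest.fixture(scope="session")
def morphology_model():
    return cc.train_morphology_model(
        cc.RenderParams(image_size=96, noise_sigma=0.02, pixel_size=0.15,
                        seed=11))


@pytest.fixture(scope="session")
def render_params():
    """Fixture-grade rendering: fine pixel scale, low noise."""
    return cc.RenderParams(pixel_size=0.15, image_size=96, noise_sigma=0.02,
                           seed=7)


def single_cell_scene(params, semi_major=1.2, ratio=0.75, orientation=0.5):
    mid = params.image_size * params.pixel_size / 2.0
    return [cc.SceneCell(0, (mid, mid), semi_major, ratio * semi_major,
                         orientation)]
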