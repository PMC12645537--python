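import numpy as np
import pytest
from hypothesis import settings

import myotrack as mt

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def cal_unit():
    return mt.Calibration(scale=1.0)


@pytest.fixture
def cal_half():
    return mt.Calibration(scale=0.5)


@pytest.fixture
def bf_profile():
    """Piecewise brightfield profile: background 200, walls 50, lumen 150.

    True mid-transitions at 39.5 (outer-left), 51.5, 111.5, 123.5."""
    vals = np.concatenate(
        [
            np.full(40, 200.0),
            np.full(12, 50.0),
            np.full(60, 150.0),
            np.full(12, 50.0),
            np.full(40, 200.0),
        ]
    )
    return mt.IntensityProfile(values=vals, origin=(0.0, 0.0), direction=(1.0, 0.0))


def straight_spec(
    od_um=200.0,
    scale=0.5,
    n_frames=1,
    frame_size=(512, 96),
    geometry="straight",
    intensities=(200.0, 50.0, 150.0),
    noise_sd=0.0,
    seed=0,
    **kw,
):
    return mt.PhantomSpec(
        geometry=geometry,
        frame_size=frame_size,
        od_track=np.full(n_frames, float(od_um)),
        calibration=mt.Calibration(scale=scale),
        intensities=intensities,
        noise_sd=noise_sd,
        seed=seed,
        **kw,
    )


@pytest.fixture
def straight_spec_factory():
    return straight_spec


@pytest.fixture
def roi_line():
    """Horizontal ROI spanning the default 512x96 phantom frame."""
    return mt.TrackLine(id=0, kind="roi_horizontal", geometry=(2, 18, 508, 60))
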