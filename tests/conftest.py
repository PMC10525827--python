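import numpy as np
import pytest

from embryokin.pose_io import BodypartScheme, StimulusRecord, TrialDesign, build_track
from embryokin.simulate import SimParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_scheme():
    return BodypartScheme(
        beak_upper="UpperBeakTip",
        beak_lower="LowerBeakTip",
        beak_fulcrum="BeakFulcrum",
        eye_corner="EyeCorner",
        reference_points=("EggRef",),
    )


def make_small_track(rng, n=20, labels=("UpperBeakTip", "LowerBeakTip", "BeakFulcrum")):
    arrays = {
        lab: np.column_stack(
            [rng.uniform(0, 500, n), rng.uniform(0, 500, n), rng.uniform(0.8, 1.0, n)]
        )
        for lab in labels
    }
    return build_track("t0", arrays)


@pytest.fixture
def small_track(rng):
    return make_small_track(rng)


@pytest.fixture
def tiny_params():
    """A fast cohort: 5 fps halves nothing scientifically but cuts frames 10x."""
    return SimParams(n_embryos=4, frame_rate=5.0)


def simple_design(embryo_id="e01", ed=16, fps=50.0, order=("Pinch", "Touch")):
    b = int(round(120 * fps))
    stim = int(round(2 * fps))
    obs = int(round(180 * fps))
    onset1 = b
    release1 = onset1 + stim
    onset2 = release1 + obs + b
    return TrialDesign(
        embryo_id=embryo_id,
        embryonic_day=ed,
        stimuli=(
            StimulusRecord(order[0], onset1, release1),
            StimulusRecord(order[1], onset2, onset2 + stim),
        ),
    )
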