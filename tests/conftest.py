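import numpy as np
import pytest

from topoerp import synth
from topoerp.containers import GroundTruth, Segment
from topoerp.montage import make_montage


@pytest.fixture(scope="session")
def montage32():
    return make_montage(32, 0)


@pytest.fixture(scope="session")
def montage64():
    return make_montage(64, 0)


@pytest.fixture(scope="session")
def null_truth(montage32):
    """Exchangeable conditions: the same two-segment sequence everywhere."""
    tpls = synth.random_templates(montage32, 2, seed=3)
    segs = [Segment(20.0, 100.0, 0, 3.0), Segment(100.0, 180.0, 1, 3.0)]
    return GroundTruth(templates=tpls,
                       segments={"direct/BB": segs, "averted/BB": segs},
                       noise_sd=10.0, seed=0)


@pytest.fixture(scope="session")
def effect_truth(montage32):
    """Different early (41-80 ms) maps for the two conditions, shared later
    maps; the planted analogue of the early gaze effect."""
    tpls = synth.random_templates(montage32, 4, seed=7)
    late = [Segment(100.0, 170.0, 2, 5.0), Segment(170.0, 260.0, 3, 5.0)]
    return GroundTruth(
        templates=tpls,
        segments={"direct/BB": [Segment(41.0, 80.0, 0, 4.0)] + late,
                  "averted/BB": [Segment(41.0, 80.0, 1, 4.0)] + late},
        noise_sd=4.0, seed=0)


def unit_noise_gfp(montage) -> float:
    """Analytic GFP of unit-sd spatially correlated noise after average
    reference: sqrt((tr C - 1'C1/n) / n) for covariance C."""
    C = np.exp(-montage.chord_distances() / synth.NOISE_RANGE)
    n = montage.n_channels
    ones = np.ones(n)
    return float(np.sqrt((np.trace(C) - ones @ C @ ones / n) / n))
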