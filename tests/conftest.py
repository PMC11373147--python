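import numpy as np
import pytest

from flightload.ocular import GazeSeries
from flightload.synthetic import EffectProfile, StudyDesign


@pytest.fixture
def small_design():
    """3 participants x 3 conditions, 30 s sessions: fast unit-test study."""
    return StudyDesign(
        n_participants=3,
        condition_difficulties=(0.1, 0.5, 0.9),
        session_duration=30.0,
        seed=7,
    )


@pytest.fixture
def default_effects():
    return EffectProfile()


@pytest.fixture
def no_variance_effects():
    """Effect profile with participant heterogeneity switched off."""
    return EffectProfile(participant_sd=0.0)


def make_gaze(t, plane_xy, valid=None, pd_mm=None):
    """GazeSeries from planar gaze coordinates (x/z, y/z projections)."""
    t = np.asarray(t, float)
    plane = np.asarray(plane_xy, float)
    dirs = np.column_stack([plane[:, 0], plane[:, 1], np.ones(len(t))])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    if valid is None:
        valid = np.ones(len(t), bool)
    if pd_mm is None:
        pd_mm = np.full(len(t), 3.5)
    return GazeSeries(
        t=t, dir=dirs, pd_left=np.asarray(pd_mm, float),
        pd_right=np.asarray(pd_mm, float), valid=np.asarray(valid, bool),
    )


def random_gaze(rng, n=200, rate=120.0, saccade_prob=0.15, step_deg=2.0):
    """Random fixation/saccade gaze walk for detector oracle comparisons."""
    t = np.arange(n) / rate
    plane = np.zeros((n, 2))
    pos = rng.uniform(-0.1, 0.1, size=2)
    for i in range(n):
        if rng.uniform() < saccade_prob:
            pos = pos + rng.normal(0, step_deg * np.pi / 180.0, size=2)
        else:
            pos = pos + rng.normal(0, 0.0002, size=2)
        plane[i] = pos
    return make_gaze(t, plane)
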