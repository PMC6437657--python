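"""Shared fixtures: scaled-down synthetic recordings and fitted pipelines.

The session-scoped recording uses the full generative structure (bursty
4-Hz transitions, waxing mid-state coupling) at sub-state durations scaled
to a 600-s trace so the whole pipeline stays fast; the study-condition
defaults themselves are exercised in the synth tests.
"""

import numpy as np
import pytest

from cfchmm.pipeline import classify_trace
from cfchmm.synth import SynthConfig, generate_lfp_with_sles


@pytest.fixture(scope="session")
def lowmg_recording():
    """Low-Mg2+-like synthetic recording, scaled sub-state durations."""
    cfg = SynthConfig(
        total_duration=600.0,
        sle_rate=1.2,
        substate_mean_durations=(8.0, 12.0, 8.0),
        substate_shape_params=(1.8, 1.6, 1.7),
        seed=3,
    )
    return generate_lfp_with_sles(cfg)


@pytest.fixture(scope="session")
def lowmg_pipeline(lowmg_recording):
    """Self-trained classification of the session recording."""
    return classify_trace(lowmg_recording.lfp, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
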