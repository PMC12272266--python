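import numpy as np
import pytest

import nirsdmst as nd

ROIS = ("lIFG", "rIFG", "ldlPFC", "rdlPFC", "SFG")


@pytest.fixture(scope="session")
def montage():
    return nd.default_montage()


@pytest.fixture(scope="session")
def exp1_plan():
    return nd.build_experiment_plan("exp1", 2, seed=11)


@pytest.fixture(scope="session")
def exp1_events(exp1_plan):
    return nd.session_events(exp1_plan.participant_blocks(0), "exp1")


@pytest.fixture(scope="session")
def exp2_plan():
    return nd.build_experiment_plan("exp2", 2, seed=12)


@pytest.fixture(scope="session")
def exp2_events(exp2_plan):
    return nd.session_events(exp2_plan.participant_blocks(0), "exp2")


def uniform_effects(events, amp=0.3):
    conds = sorted(events.loc[events.phase == "S1", "condition"].unique())
    return {(r, c): amp for r in ROIS for c in conds}


@pytest.fixture(scope="session")
def noiseless_exp1(exp1_events, montage):
    """Noiseless simulated recording with its ground truth."""
    fwd = nd.ForwardConfig(effects=uniform_effects(exp1_events),
                           anchor="s1", window_start_s=-5.0)
    hb, gt = nd.simulate_hb(exp1_events, montage, fwd,
                            np.random.default_rng(0))
    return hb, gt, fwd
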