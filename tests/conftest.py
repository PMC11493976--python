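import numpy as np
import pytest

from confcontrol import accumulators as acc
from confcontrol import stimuli as st
from confcontrol import synthetic as syn


@pytest.fixture(scope="session")
def condition_set():
    return st.make_condition_set()


@pytest.fixture(scope="session")
def stimulus_bank():
    """Small shared bank: 2 stimuli per condition (one per side)."""
    traces, manifest = syn.make_stimulus_bank(per_condition=2, seed=1)
    return traces


@pytest.fixture(scope="session")
def default_params():
    return acc.ConfControlParams(sigma=1.2, beta=2.0, t_d=1.0, b=6.0,
                                 mu_U=0.3, sigma_U=0.15)


@pytest.fixture(scope="session")
def moderate_trace(stimulus_bank):
    return next(t for k, t in stimulus_bank.items()
                if k.startswith("stable-moderate/left"))


@pytest.fixture(scope="session")
def small_subject(stimulus_bank, default_params):
    """One synthetic subject, 20 trials per condition."""
    return syn.generate_subject(default_params, stimulus_bank, 20, "s0",
                                seed=11)
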