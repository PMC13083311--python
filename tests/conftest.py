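import numpy as np
import pandas as pd
import pytest

from sspflanker import SimulationConfig, SSPParameters, START_MEANS
from sspflanker.fitting import FitProfile


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


@pytest.fixture
def sim_config():
    return SimulationConfig()


@pytest.fixture
def mean_params():
    """An observer at the published start-distribution means."""
    return SSPParameters(*START_MEANS)


@pytest.fixture
def mini_profile():
    """A very small fit profile for smoke/contract tests (not for accuracy)."""
    return FitProfile(
        n_starts=2,
        n_sim=500,
        maxiter=30,
        explore_n_sim=500,
        explore_maxiter=30,
        n_polish=1,
        polish_sizes=(0.3,),
        select_n_sim=500,
        final_maxiter=0,
    )


def make_trials(rt_correct, rt_error, congruency="congruent", participant="P01", condition="C"):
    """Hand-built trial table from explicit RT lists."""
    rts = list(rt_correct) + list(rt_error)
    acc = [1] * len(rt_correct) + [0] * len(rt_error)
    return pd.DataFrame(
        {
            "participant": participant,
            "condition": condition,
            "congruency": congruency,
            "rt_ms": np.asarray(rts, dtype=float),
            "accuracy": acc,
            "responded": True,
        }
    )
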