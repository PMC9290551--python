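"""Shared fixtures: small simulated datasets built at test time."""

import numpy as np
import pandas as pd
import pytest

from neurofuse import task


def simulate_trials(n_trials=80, n_sessions=1, seed=0, participant=None,
                    agent=None, config_kwargs=None):
    cfg = task.TaskConfig(n_sessions=n_sessions,
                          trials_per_session=n_trials, n_blocks=1,
                          rng_seed=seed, **(config_kwargs or {}))
    trials = task.simulate_agent(task.build_schedule(cfg),
                                 agent or task.AgentParams(), seed=seed + 1)
    trials = task.assign_outcomes(trials, cfg, seed=seed + 2)
    if participant is not None:
        trials["participant"] = participant
    return trials


@pytest.fixture(scope="session")
def small_trials():
    """One 80-trial session from the default biased agent."""
    return simulate_trials(n_trials=80, seed=3)


@pytest.fixture(scope="session")
def multi_pp_trials():
    """12 participants x 320 trials with the default motivational bias."""
    frames = [simulate_trials(n_trials=320, seed=100 + p, participant=p)
              for p in range(12)]
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def multi_pp_null_trials():
    """12 participants with no valence bias (null for the bias test)."""
    agent = task.AgentParams(go_bias_valence=0.0, rt_valence_shift_ms=0.0)
    frames = [simulate_trials(n_trials=320, seed=200 + p, participant=p,
                              agent=agent)
              for p in range(12)]
    return pd.concat(frames, ignore_index=True)


def toy_trials(n=64, seed=0, all_correct=True):
    """Balanced, fully factorial toy trial table (no timing columns)."""
    rng = np.random.default_rng(seed)
    val = np.tile(np.repeat(["win", "avoid"], 2), n // 4)
    req = np.tile(["go_left", "nogo"], n // 2)
    resp = req.copy()
    df = pd.DataFrame({
        "session": 0,
        "valence": val,
        "required_action": req,
        "response": resp,
        "rt_ms": np.where(resp != "nogo",
                          rng.uniform(400, 1000, size=n), np.nan),
        "accuracy": "correct" if all_correct else
                    rng.choice(["correct", "incorrect"], size=n),
        "congruency": np.where((val == "win") == (req != "nogo"),
                               "congruent", "incongruent"),
        "invalid_press": False,
    })
    df["is_go"] = df["response"] != "nogo"
    return df
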