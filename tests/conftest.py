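"""Shared fixtures: small simulated sessions and cohorts.

Everything is generated programmatically at collection time from fixed
seeds; no data files ship with the package.
"""

from __future__ import annotations

import numpy as np
import pytest

from explorebandit import task as tk
from explorebandit.likelihood import compile_session
from explorebandit.models import get_model


@pytest.fixture(scope="session")
def default_task():
    return tk.generate_task(tk.TaskConfig(), seed=11)


@pytest.fixture(scope="session")
def famgate_session(default_task):
    """One familiarity-gated uncertainty-averse agent with injected
    missed/fast trials."""
    return tk.simulate_agent(
        default_task,
        get_model("familiarity_gate"),
        {"beta_sm": 8.0, "eta": 0.7, "w_unc": -1.0},
        seed=21,
        participant_id="fg_1",
        miss_rate=0.02,
        fast_rate=0.02,
    )


@pytest.fixture(scope="session")
def famgate_compiled(famgate_session):
    return compile_session(famgate_session.trials, "fg_1")


def simulate_group(model_name, params_fn, n, seed0, age=25.0):
    """n agents of one model; ``params_fn(rng)`` draws per-subject params."""
    model = get_model(model_name)
    rng = np.random.default_rng(seed0)
    sessions = []
    for i in range(n):
        task = tk.generate_task(tk.TaskConfig(), 100_000 + 1000 * seed0 + i)
        sessions.append(
            tk.simulate_agent(
                task,
                model,
                params_fn(rng),
                seed=200_000 + 1000 * seed0 + i,
                participant_id=f"s{i:03d}",
                age_years=age,
            )
        )
    return sessions


@pytest.fixture(scope="session")
def novelty_cohort_sessions():
    """30 child-like novelty-bias agents at the study's generating values."""
    return simulate_group(
        "novelty_bias",
        lambda rng: {
            "beta_sm": 6.0,
            "eta": 0.7,
            "novelty_bias": float(rng.normal(1.49, 0.5)),
        },
        n=30,
        seed0=1,
        age=10.0,
    )
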