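import math

import numpy as np
import pytest

from rgtlearn import AgentState, TaskConfig, TraitParams, run_session
from rgtlearn.session import SessionRecord


@pytest.fixture(scope="session")
def config() -> TaskConfig:
    return TaskConfig.default()


@pytest.fixture(scope="session")
def good_params() -> TraitParams:
    """Neutral-trait agent: sustained learning, no reward/risk distortion."""
    return TraitParams(alpha0=0.3, tau0=math.inf, omega=1.0, rho=0.0, epsilon=0.5)


@pytest.fixture(scope="session")
def poor_params() -> TraitParams:
    """Trait-loaded agent: reward seeking, risk seeking, decaying learning."""
    return TraitParams(alpha0=0.2, tau0=600.0, omega=2.0, rho=1.0, epsilon=1.0)


@pytest.fixture(scope="session")
def good_session(config, good_params) -> SessionRecord:
    return run_session(config, good_params, 1)


def make_record(config, starts, options, pellets=None, penalties=None):
    """Hand-built session record for binning/classification tests."""
    starts = np.asarray(starts, dtype=float)
    options = np.asarray(options, dtype=np.int64)
    n = len(starts)
    if pellets is None:
        pellets = np.array([config.reward_pellets[o] for o in options])
    if penalties is None:
        penalties = np.zeros(n, dtype=bool)
    pen_vals = np.where(penalties, [config.penalty_pellets[o] for o in options], 0.0)
    inv = config.option_to_hole
    return SessionRecord(
        start_seconds=starts,
        hole=np.array([inv[o] for o in options]),
        option=options,
        pellets=np.asarray(pellets),
        penalty_applied=np.asarray(penalties, dtype=bool),
        penalty_pellets=pen_vals,
        params_used=TraitParams(alpha0=0.3),
        config_used=config,
        final_state=AgentState.initial(config.n_options),
        rng_seed=None,
    )
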