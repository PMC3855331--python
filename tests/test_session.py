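import math

import numpy as np
import pytest

from rgtlearn import (
    AgentState,
    TraitParams,
    UnclassifiableSessionError,
    bin_profile,
    classify_flexibility,
    classify_rgt,
    flexibility_score,
    preferred_contingency,
    run_reversal_session,
    run_session,
    update_value,
)
from rgtlearn.task import TrialOutcome

from conftest import make_record


def test_same_seed_reproduces_session(config, good_params):
    a = run_session(config, good_params, 11)
    b = run_session(config, good_params, 11)
    assert np.array_equal(a.start_seconds, b.start_seconds)
    assert np.array_equal(a.option, b.option)
    assert np.array_equal(a.penalty_applied, b.penalty_applied)
    assert a.final_state.q_values == pytest.approx(b.final_state.q_values)


def test_forced_advantageous_policy_hits_pellet_cap(config, good_params):
    rec = run_session(config, good_params, 0, forced_hole=2)
    assert rec.final_state.pellets_earned == config.pellet_cap
    assert rec.final_state.elapsed_seconds < config.session_seconds
    assert rec.n_trials == config.pellet_cap  # one pellet per C trial


def test_session_loop_matches_stepwise_agent_updates(config, poor_params):
    """Replaying the trial log through the public per-trial update API
    reproduces the session core's final learner state exactly."""
    rec = run_session(config, poor_params, 5)
    state = AgentState.initial(config.n_options)
    for t, h, o, r, pen, x in zip(
        rec.start_seconds, rec.hole, rec.option, rec.pellets,
        rec.penalty_applied, rec.penalty_pellets,
    ):
        state.elapsed_seconds = t
        elapsed = config.episode_seconds * r + (config.timeout_seconds[o] if pen else 0.0)
        update_value(state, poor_params, int(h), TrialOutcome(int(o), int(r), bool(pen), float(x), elapsed))
    assert state.q_values == pytest.approx(rec.final_state.q_values, rel=1e-12, abs=1e-12)
    assert np.array_equal(state.penalty_n, rec.final_state.penalty_n)
    assert state.penalty_m2 == pytest.approx(rec.final_state.penalty_m2, rel=1e-9)


def test_bin_profile_all_advantageous(config, good_params):
    rec = run_session(config, good_params, 2, forced_hole=3)
    prof = bin_profile(rec)
    defined = ~np.isnan(prof.percent)
    assert np.all(prof.percent[defined] == 100.0)
    assert prof.counts.sum() == rec.n_trials


def test_bin_assignment_is_half_open(config):
    rec = make_record(config, starts=[0.0, 599.999, 600.0, 3599.0], options=[2, 0, 2, 2])
    prof = bin_profile(rec)
    assert list(prof.counts) == [2, 1, 0, 0, 0, 1]
    assert prof.percent[0] == pytest.approx(50.0)
    assert prof.percent[1] == pytest.approx(100.0)
    assert math.isnan(prof.percent[2])


def test_last20_pools_trials_rather_than_averaging_bins(config):
    # bin 5: 1 of 1 advantageous; bin 6: 1 of 3 -> pooled 2/4 = 50%,
    # whereas the mean of the bin percentages would be (100 + 33.3)/2
    rec = make_record(
        config,
        starts=[2500.0, 3000.0, 3100.0, 3200.0],
        options=[2, 3, 0, 1],
    )
    prof = bin_profile(rec)
    assert prof.last20_percent == pytest.approx(50.0)
    assert prof.last20_count == 4


def test_empty_record_is_degenerate(config):
    rec = make_record(config, starts=[], options=[])
    with pytest.raises(UnclassifiableSessionError):
        bin_profile(rec)


@pytest.mark.parametrize(
    "last20, label",
    [(85.0, "good"), (20.0, "poor"), (70.0, "undecided"), (30.0, "undecided"), (50.0, "undecided")],
)
def test_classification_bounds_are_strict(config, last20, label):
    rec = make_record(config, starts=[3000.0], options=[2])
    prof = bin_profile(rec)
    prof.last20_percent = last20
    assert classify_rgt(prof) == label


def test_classification_requires_final_window_trials(config):
    rec = make_record(config, starts=[100.0], options=[2])
    prof = bin_profile(rec)
    with pytest.raises(UnclassifiableSessionError):
        classify_rgt(prof)


def test_session_invariants_over_random_parameters(config):
    """Clock cap, pellet cap, ordering, and bin bookkeeping hold across
    the whole parameter space."""
    rng = np.random.default_rng(12)
    for _ in range(1000):
        k = rng.uniform(0.0, 1.0 / 60.0)
        params = TraitParams(
            alpha0=rng.uniform(0.01, 1.0),
            tau0=math.inf if k == 0 else 1.0 / k,
            omega=rng.uniform(0.5, 4.0),
            rho=rng.uniform(-1.0, 2.0),
            epsilon=rng.uniform(0.05, 5.0),
        )
        rec = run_session(config, params, rng)
        assert np.all(np.diff(rec.start_seconds) > 0)
        assert rec.start_seconds[-1] < config.session_seconds
        assert rec.final_state.pellets_earned <= config.pellet_cap + 1
        prof = bin_profile(rec)
        assert prof.counts.sum() == rec.n_trials
        defined = ~np.isnan(prof.percent)
        assert np.all((prof.percent[defined] >= 0) & (prof.percent[defined] <= 100))


def test_reward_seeking_extremes_reduce_advantageous_choice(config):
    """With a positive risk coefficient, strong reward over-valuation
    drags performance down (common random numbers across the sweep)."""
    seeds = range(1, 41)
    means = []
    for omega in (1.0, 3.0):
        p = TraitParams(alpha0=0.3, tau0=math.inf, omega=omega, rho=1.0, epsilon=0.5)
        vals = [bin_profile(run_session(config, p, s)).last20_percent for s in seeds]
        means.append(np.nanmean(vals))
    assert means[1] < means[0]


# -- reversal ------------------------------------------------------------

def test_reversal_without_learning_keeps_values(config):
    p = TraitParams(alpha0=1e-9, tau0=math.inf, omega=1.0, rho=0.0, epsilon=0.5)
    rgt = run_session(config, p, 3)
    carried = rgt.final_state.copy()
    rev = run_reversal_session(config, p, carried, 4)
    assert rev.final_state.q_values == pytest.approx(rgt.final_state.q_values, abs=1e-4)
    assert rev.config_used.hole_to_option == (2, 3, 0, 1)


def test_reversal_carries_state_and_resets_clocks(config, good_params):
    rgt = run_session(config, good_params, 3)
    rev = run_reversal_session(config, good_params, rgt.final_state.copy(), 4)
    assert rev.start_seconds[0] < config.forced_exploration_seconds
    assert rev.final_state.penalty_n.sum() >= rgt.final_state.penalty_n.sum()


def test_flexible_archetype_retracks_preference(config):
    p = TraitParams(alpha0=0.5, tau0=math.inf, omega=1.0, rho=0.0, epsilon=0.5)
    scores = []
    for s in range(1, 21):
        rgt = run_session(config, p, s)
        rev = run_reversal_session(config, p, rgt.final_state.copy(), 1000 + s)
        scores.append(flexibility_score(rev, preferred_contingency(rgt)))
    assert np.mean(scores) > 60.0


def test_inflexible_archetype_perseverates(config):
    p = TraitParams(alpha0=0.5, tau0=120.0, omega=1.0, rho=0.0, epsilon=0.5)
    scores = []
    for s in range(1, 21):
        rgt = run_session(config, p, s)
        rev = run_reversal_session(config, p, rgt.final_state.copy(), 1000 + s)
        scores.append(flexibility_score(rev, preferred_contingency(rgt)))
    assert np.mean(scores) < 40.0


def test_flexibility_score_extremes_and_categories(config):
    rev_cfg = run_reversal_session(
        config, TraitParams(alpha0=1e-9), AgentState.initial(), 0
    ).config_used
    full = make_record(rev_cfg, starts=[2500.0, 3000.0], options=[2, 3])
    assert flexibility_score(full, "advantageous") == 100.0
    assert classify_flexibility(100.0) == "flexible"
    none = make_record(rev_cfg, starts=[2500.0, 3000.0], options=[0, 1])
    assert flexibility_score(none, "advantageous") == 0.0
    assert classify_flexibility(0.0) == "inflexible"
    assert classify_flexibility(50.0) == "undecided"
    assert classify_flexibility(40.0) == "undecided"
    assert classify_flexibility(60.0) == "undecided"
    early_only = make_record(rev_cfg, starts=[100.0], options=[2])
    with pytest.raises(UnclassifiableSessionError):
        flexibility_score(early_only, "advantageous")


def test_session_csv_roundtrip(config, good_session, tmp_path):
    path = tmp_path / "session.csv"
    good_session.to_csv(path)
    import pandas as pd

    df = pd.read_csv(path)
    assert len(df) == good_session.n_trials
    assert set(df.columns) >= {"t_start_s", "hole", "option", "pellets", "penalty_applied"}
    assert df["option"].isin(list(config.option_labels)).all()
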