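import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rgtlearn import (
    AgentState,
    TraitParams,
    action_probabilities,
    area_under_learning_rate,
    effective_signal,
    expected_outcome_value,
    learning_rate_at,
    risk_level,
    sample_outcome,
    select_action,
    update_value,
)
from rgtlearn.task import TrialOutcome


def _params(**kw):
    base = dict(alpha0=0.3, tau0=math.inf, omega=1.0, rho=0.0, epsilon=0.5)
    base.update(kw)
    return TraitParams(**base)


# -- learning-rate decay -------------------------------------------------

def test_learning_rate_examples():
    assert learning_rate_at(_params(alpha0=0.5), 3600.0) == 0.5  # no decay limit
    assert learning_rate_at(_params(alpha0=0.7, tau0=100.0), 0.0) == 0.7
    assert learning_rate_at(_params(alpha0=0.5, tau0=600.0), 600.0) == pytest.approx(
        0.5 * math.exp(-1), rel=1e-12
    )
    with pytest.raises(ValueError):
        learning_rate_at(_params(), -1.0)


def test_learning_rate_monotone_and_bounded():
    p = _params(alpha0=0.8, tau0=300.0)
    rates = [learning_rate_at(p, t) for t in np.linspace(0, 3600, 50)]
    assert all(0 < r <= p.alpha0 for r in rates)
    assert all(a >= b for a, b in zip(rates, rates[1:]))


def test_flexibility_index_increases_with_both_parameters():
    base = area_under_learning_rate(_params(alpha0=0.4, tau0=600.0))
    assert area_under_learning_rate(_params(alpha0=0.5, tau0=600.0)) > base
    assert area_under_learning_rate(_params(alpha0=0.4, tau0=900.0)) > base
    assert area_under_learning_rate(_params(alpha0=0.4)) == pytest.approx(0.4 * 3600)


def test_trait_params_validation_and_json(tmp_path):
    with pytest.raises(ValueError):
        TraitParams(alpha0=0.0)
    with pytest.raises(ValueError):
        TraitParams(alpha0=0.5, tau0=-1.0)
    with pytest.raises(ValueError):
        TraitParams(alpha0=0.5, epsilon=0.0)
    p = _params(tau0=math.inf)
    path = tmp_path / "p.json"
    p.to_json(path)
    assert TraitParams.from_json(path) == p


# -- risk statistic ------------------------------------------------------

def _push_penalty(state, hole, value, config):
    out = TrialOutcome(hole, 1, value != 0.0, value, 9.0)
    update_value(state, _params(alpha0=1e-12), hole, out)


def test_risk_level_degenerate_and_two_point(config):
    state = AgentState.initial()
    assert risk_level(state, 0) == 0.0
    _push_penalty(state, 0, -50.0, config)
    assert risk_level(state, 0) == 0.0  # single observation
    _push_penalty(state, 0, 0.0, config)
    assert risk_level(state, 0) == pytest.approx(25.0)  # population SD of {-50, 0}


@settings(derandomize=True, max_examples=30)
@given(st.lists(st.sampled_from([0.0, -50.0, -25.0, -4.0 / 3.0]), min_size=2, max_size=60))
def test_running_risk_matches_brute_force(history):
    """Welford running spread equals a fresh recomputation at every step."""
    state = AgentState.initial()
    p = _params(alpha0=1e-12)
    for i, x in enumerate(history):
        out = TrialOutcome(1, 1, x != 0.0, x, 9.0)
        update_value(state, p, 1, out)
        expected = float(np.std(history[: i + 1]))
        assert risk_level(state, 1) == pytest.approx(expected, rel=1e-9, abs=1e-12)


def test_asymptotic_risk_matches_bernoulli_sd(config):
    """Long sampling recovers sd = |penalty| * sqrt(p(1-p)): 25 for A,
    25*sqrt(3)/4 for B."""
    rng = np.random.default_rng(3)
    for option, expected in ((0, 25.0), (1, 25.0 * math.sqrt(3) / 4.0)):
        state = AgentState.initial()
        p = _params(alpha0=1e-12)
        for _ in range(10_000):
            update_value(state, p, option, sample_outcome(config, option, rng))
        assert risk_level(state, option) == pytest.approx(expected, rel=0.05)


# -- learning signal and value update ------------------------------------

def test_effective_signal_examples(config):
    rng = np.random.default_rng(0)
    no_pen = TrialOutcome(2, 1, False, 0.0, 9.0)
    assert effective_signal(_params(), no_pen, risk=0.0) == 1.0
    a_pen = TrialOutcome(0, 2, True, -50.0, 462.0)
    assert effective_signal(_params(omega=2, rho=1), a_pen, risk=25.0) == pytest.approx(-21.0)
    a_clean = TrialOutcome(0, 2, False, 0.0, 18.0)
    assert effective_signal(_params(omega=2, rho=1), a_clean, risk=25.0) == pytest.approx(29.0)


def test_full_step_update_sets_value_to_signal():
    state = AgentState.initial()
    state.q_values[2] = 5.0
    out = TrialOutcome(2, 1, False, 0.0, 9.0)
    update_value(state, _params(alpha0=1.0), 2, out)
    assert state.q_values[2] == pytest.approx(1.0)  # signal replaces prior value


def test_vanishing_learning_rate_freezes_values():
    state = AgentState.initial()
    state.q_values[:] = [1.0, 2.0, 3.0, 4.0]
    state.elapsed_seconds = 1e6
    out = TrialOutcome(0, 2, True, -50.0, 462.0)
    update_value(state, _params(alpha0=0.5, tau0=1.0), 0, out)
    assert state.q_values == pytest.approx([1.0, 2.0, 3.0, 4.0])
    assert state.penalty_n[0] == 1  # the experience is still recorded


def test_update_only_touches_chosen_hole():
    state = AgentState.initial()
    out = TrialOutcome(1, 2, False, 0.0, 18.0)
    update_value(state, _params(alpha0=0.5), 1, out)
    assert state.q_values[1] != 0.0
    assert state.q_values[[0, 2, 3]] == pytest.approx([0.0, 0.0, 0.0])
    assert list(state.penalty_n) == [0, 1, 0, 0]


@pytest.mark.parametrize("option", [0, 1, 2, 3])
def test_td_converges_to_expected_value_oracle(config, option):
    """With neutral traits and small constant alpha, the time-averaged
    value of a repeatedly forced option settles at its closed-form
    expectation (2/3, 2/3, -23, -4.25)."""
    rng = np.random.default_rng(10 + option)
    p = _params(alpha0=0.05)
    state = AgentState.initial()
    trace = []
    for i in range(6000):
        update_value(state, p, option, sample_outcome(config, option, rng))
        if i >= 3000:
            trace.append(state.q_values[option])
    ev = expected_outcome_value(config, option)
    assert np.mean(trace) == pytest.approx(ev, abs=max(0.1, 0.05 * abs(ev)))


def test_risk_seeking_raises_asymptotic_valuation(config):
    """rho > 0 adds rho * (Bernoulli penalty SD) to the fixed point."""
    rng = np.random.default_rng(4)
    p = _params(alpha0=0.05, rho=1.0)
    for option, sd in ((0, 25.0), (1, 25.0 * math.sqrt(3) / 4.0)):
        state = AgentState.initial()
        trace = []
        for i in range(8000):
            update_value(state, p, option, sample_outcome(config, option, rng))
            if i >= 4000:
                trace.append(state.q_values[option])
        expected = expected_outcome_value(config, option) + 1.0 * sd
        assert np.mean(trace) == pytest.approx(expected, abs=max(0.6, 0.05 * abs(expected)))


# -- softmax choice ------------------------------------------------------

def test_softmax_uniform_for_equal_values():
    state = AgentState.initial()
    p = action_probabilities(state, _params(epsilon=1.0))
    assert p == pytest.approx([0.25] * 4)


def test_softmax_two_value_closed_form():
    state = AgentState.initial()
    state.q_values[:] = [1.0, 0.0, -1e9, -1e9]
    p = action_probabilities(state, _params(epsilon=1.0))
    assert p[0] == pytest.approx(math.e / (1 + math.e), rel=1e-6)
    assert p[1] == pytest.approx(1 / (1 + math.e), rel=1e-6)


def test_softmax_high_temperature_approaches_uniform():
    state = AgentState.initial()
    state.q_values[:] = [3.0, -2.0, 1.0, 0.0]
    p = action_probabilities(state, _params(epsilon=1e4))
    assert p == pytest.approx([0.25] * 4, abs=1e-3)


def test_softmax_numerically_stable_at_extreme_values():
    state = AgentState.initial()
    state.q_values[:] = [1000.0, 0.0, -1000.0, 500.0]
    p = action_probabilities(state, _params(epsilon=1.0))
    assert np.all(np.isfinite(p))
    assert p.sum() == pytest.approx(1.0)
    assert p[0] == pytest.approx(1.0)


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(st.floats(min_value=-50, max_value=50), min_size=4, max_size=4),
    st.floats(min_value=0.05, max_value=5.0),
    st.floats(min_value=-20, max_value=20),
)
def test_softmax_properties(qs, eps, shift):
    """Probabilities are a distribution and invariant to common shifts."""
    state = AgentState.initial()
    state.q_values[:] = qs
    p = action_probabilities(state, _params(epsilon=eps))
    assert p.sum() == pytest.approx(1.0)
    # mathematically p lies in (0,1); in floating point extreme value gaps
    # can round an entry to 0 or 1, so only the closed bounds are asserted
    assert np.all(p >= 0) and np.all(p <= 1)
    if np.ptp(qs) / eps < 30:
        assert np.all(p > 0) and np.all(p < 1)
    state.q_values[:] = np.asarray(qs) + shift
    p2 = action_probabilities(state, _params(epsilon=eps))
    assert p2 == pytest.approx(p, rel=1e-6, abs=1e-12)


def test_forced_exploration_is_uniform():
    state = AgentState.initial()
    state.q_values[:] = [10.0, 0.0, 0.0, 0.0]  # values must be ignored
    rng = np.random.default_rng(6)
    n = 10_000
    counts = np.bincount(
        [select_action(state, _params(), rng, in_forced_exploration=True) for _ in range(n)],
        minlength=4,
    )
    se = math.sqrt(0.25 * 0.75 / n)
    assert np.all(np.abs(counts / n - 0.25) < 4 * se)


def test_greedy_selection_with_sharp_temperature():
    state = AgentState.initial()
    state.q_values[:] = [10.0, 0.0, 0.0, 0.0]
    rng = np.random.default_rng(7)
    picks = {select_action(state, _params(epsilon=0.1), rng) for _ in range(1000)}
    assert picks == {0}
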