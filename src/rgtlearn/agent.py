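"""Trait-augmented temporal-difference learner.

A standard TD value learner over the four hole-indexed actions, extended
with three behavioural traits, each carried by one parameter of
:class:`TraitParams`:

* **cognitive inflexibility** — the learning rate decays exponentially over
  the session, ``alpha(t) = alpha0 * exp(-t / tau0)``; a short time constant
  freezes learning early, so pre-reversal preferences persist.  The
  time-integral of ``alpha`` over the session is a global flexibility index.
* **reward seeking** — delivered rewards enter the learning signal scaled
  by a multiplicative weight ``omega`` (``omega > 1``: subjective
  over-valuation).  Penalty sensitivity is deliberately NOT scaled.
* **risk seeking** — an additive bonus ``rho * risk`` where the risk level
  of an action is the running standard deviation of the penalty values
  experienced each time that action was taken (zero-penalty trials
  included).  ``rho > 0`` makes high-variance options attractive.

Action selection is softmax over the hole values with temperature
``epsilon``; during the forced-exploration phase at the start of a session
choices are uniform.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .task import TrialOutcome

__all__ = [
    "TraitParams",
    "AgentState",
    "learning_rate_at",
    "area_under_learning_rate",
    "risk_level",
    "effective_signal",
    "update_value",
    "action_probabilities",
    "select_action",
]


@dataclass(frozen=True)
class TraitParams:
    """One individual's model parameters.

    Attributes
    ----------
    alpha0 : float
        Initial learning rate, in (0, 1].
    tau0 : float
        Learning-rate decay time constant in seconds (> 0); ``inf`` means a
        constant learning rate (no inflexibility).
    omega : float
        Reward-seeking multiplicative weight, >= 0; neutral value 1.
    rho : float
        Risk coefficient; > 0 risk-seeking, < 0 risk-averse, neutral 0.
    epsilon : float
        Softmax temperature, > 0.
    """

    alpha0: float
    tau0: float = math.inf
    omega: float = 1.0
    rho: float = 0.0
    epsilon: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha0 <= 1.0:
            raise ValueError(f"alpha0 must be in (0, 1], got {self.alpha0}")
        if not self.tau0 > 0:
            raise ValueError(f"tau0 must be > 0, got {self.tau0}")
        if self.omega < 0:
            raise ValueError(f"omega must be >= 0, got {self.omega}")
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")

    def to_dict(self) -> dict:
        return {
            "alpha0": self.alpha0,
            "tau0": "inf" if math.isinf(self.tau0) else self.tau0,
            "omega": self.omega,
            "rho": self.rho,
            "epsilon": self.epsilon,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TraitParams":
        kw = dict(d)
        if kw.get("tau0") == "inf":
            kw["tau0"] = math.inf
        return cls(**kw)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TraitParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class AgentState:
    """Mutable per-session learner state, indexed by physical hole.

    ``penalty_n/mean/m2`` hold Welford running statistics of the penalty
    values experienced at each hole (zeros included), from which the risk
    level is read off as a population standard deviation.
    """

    q_values: np.ndarray
    penalty_n: np.ndarray
    penalty_mean: np.ndarray
    penalty_m2: np.ndarray
    elapsed_seconds: float = 0.0
    pellets_earned: int = 0

    @classmethod
    def initial(cls, n_holes: int = 4) -> "AgentState":
        """Fresh state: all action values zero, no penalty history."""
        return cls(
            q_values=np.zeros(n_holes),
            penalty_n=np.zeros(n_holes, dtype=np.int64),
            penalty_mean=np.zeros(n_holes),
            penalty_m2=np.zeros(n_holes),
        )

    def copy(self) -> "AgentState":
        return AgentState(
            self.q_values.copy(),
            self.penalty_n.copy(),
            self.penalty_mean.copy(),
            self.penalty_m2.copy(),
            self.elapsed_seconds,
            self.pellets_earned,
        )


def learning_rate_at(params: TraitParams, t_seconds: float) -> float:
    """Learning rate at session time ``t_seconds``.

    Exponential decay from ``alpha0`` with time constant ``tau0``;
    ``tau0 = inf`` gives a constant rate.
    """
    if t_seconds < 0:
        raise ValueError(f"t_seconds must be >= 0, got {t_seconds}")
    if math.isinf(params.tau0):
        return params.alpha0
    return params.alpha0 * math.exp(-t_seconds / params.tau0)


def area_under_learning_rate(params: TraitParams, duration_seconds: float = 3600.0) -> float:
    """Integral of the learning rate over the session — the global
    flexibility index.  Increasing in both ``alpha0`` and ``tau0``."""
    if math.isinf(params.tau0):
        return params.alpha0 * duration_seconds
    return params.alpha0 * params.tau0 * (1.0 - math.exp(-duration_seconds / params.tau0))


def risk_level(state: AgentState, hole: int) -> float:
    """Risk level of ``hole``: population SD of its experienced penalties.

    Zero until the hole has been chosen at least twice.
    """
    n = int(state.penalty_n[hole])
    if n <= 1:
        return 0.0
    return math.sqrt(state.penalty_m2[hole] / n)


def effective_signal(params: TraitParams, outcome: TrialOutcome, risk: float) -> float:
    """Subjective learning signal for one trial.

    ``omega`` scales only the delivered reward (penalty sensitivity is held
    constant across individuals); the risk bonus ``rho * risk`` is additive.
    """
    return params.omega * outcome.pellets + outcome.penalty_pellets + params.rho * risk


def update_value(
    state: AgentState,
    params: TraitParams,
    hole: int,
    outcome: TrialOutcome,
) -> AgentState:
    """Apply one trial's learning update to ``state`` (in place).

    The penalty statistic for the chosen hole is updated first — the
    current trial's penalty (0 if none) informs the current risk bonus —
    then the hole's value moves toward the effective signal by the
    learning rate at the current session time.  The session clock is NOT
    advanced here; the session driver owns time accounting.
    """
    x = outcome.penalty_pellets
    n = int(state.penalty_n[hole]) + 1
    state.penalty_n[hole] = n
    d = x - state.penalty_mean[hole]
    state.penalty_mean[hole] += d / n
    state.penalty_m2[hole] += d * (x - state.penalty_mean[hole])

    risk = risk_level(state, hole)
    signal = effective_signal(params, outcome, risk)
    alpha = learning_rate_at(params, state.elapsed_seconds)
    state.q_values[hole] += alpha * (signal - state.q_values[hole])
    return state


def action_probabilities(
    state: AgentState,
    params: TraitParams,
    available: np.ndarray | None = None,
) -> np.ndarray:
    """Softmax choice probabilities over hole values.

    ``p(h) ∝ exp(Q[h] / epsilon)`` over the available holes, computed with
    a max-shift so it is stable for ``|Q|/epsilon`` of order 1e3 and
    invariant under adding a constant to all values.
    """
    q = state.q_values
    if available is None:
        available = np.ones(len(q), dtype=bool)
    z = q[available] / params.epsilon
    z = z - z.max()
    w = np.exp(z)
    p = np.zeros(len(q))
    p[available] = w / w.sum()
    return p


def select_action(
    state: AgentState,
    params: TraitParams,
    rng: np.random.Generator,
    in_forced_exploration: bool = False,
) -> int:
    """Draw a hole: uniformly during forced exploration, softmax otherwise.

    Sampling inverts the cumulative distribution with a single uniform
    draw, so exact ties between values are resolved by the draw, never by
    hole order.
    """
    n = len(state.q_values)
    u = rng.random()
    if in_forced_exploration:
        return min(int(u * n), n - 1)
    p = action_probabilities(state, params)
    return int(np.searchsorted(np.cumsum(p), u * p.sum(), side="right").clip(0, n - 1))
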