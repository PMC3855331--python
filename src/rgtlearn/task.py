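"""The Rat Gambling Task (RGT) as a Markov decision process.

The RGT is a four-option operant task: in a one-hour session a rat chooses
freely among four nose-poke holes.  Two options (A, B) deliver two food
pellets immediately but carry long, probabilistic time-out penalties; the
other two (C, D) deliver one pellet with short, rare time-outs, and are the
better choices in the long run.  A time-out of ``d`` seconds is equivalent
to forgoing ``d / episode_seconds`` pellets, which converts the task to a
pellet-unit reward/penalty scheme a learning agent can be trained on.

This module defines the task configuration (contingency table, timing,
session caps), outcome sampling, the closed-form expected value of each
option, and the spatially-reversed variant used to probe behavioural
flexibility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources
import numpy as np

__all__ = [
    "OPTION_LABELS",
    "TaskConfig",
    "TrialOutcome",
    "convert_timeout_to_penalty",
    "sample_outcome",
    "expected_outcome_value",
    "make_reversed",
]

#: Canonical option order.  Index 0..3 <-> labels A..D everywhere.
OPTION_LABELS: tuple[str, ...] = ("A", "B", "C", "D")

_REVERSAL_SWAP = (2, 3, 0, 1)  # A<->C, B<->D


def convert_timeout_to_penalty(timeout_seconds: float, episode_seconds: float) -> float:
    """Express a time-out as an equivalent immediate pellet loss.

    During a time-out no food can be obtained; since one pellet is obtained
    and consumed in ``episode_seconds`` on average, a time-out of duration
    ``timeout_seconds`` is worth ``-timeout_seconds / episode_seconds``
    pellets.

    Parameters
    ----------
    timeout_seconds : float
        Duration of the time-out, >= 0.
    episode_seconds : float
        Mean time to obtain and consume one pellet, > 0.

    Returns
    -------
    float
        Non-positive penalty in pellet units.
    """
    if episode_seconds <= 0:
        raise ValueError(f"episode_seconds must be > 0, got {episode_seconds}")
    if timeout_seconds < 0:
        raise ValueError(f"timeout_seconds must be >= 0, got {timeout_seconds}")
    return -timeout_seconds / episode_seconds


@dataclass(frozen=True)
class TaskConfig:
    """Contingency table and timing of one RGT (or reversed-RGT) session.

    ``hole_to_option[h]`` gives the option (contingency) index currently
    assigned to physical hole ``h``.  In the standard RGT this is the
    identity; in the reversal condition the holes carrying the {A, B}
    contingencies are exchanged with those carrying {C, D} while the
    contingencies themselves are untouched.
    """

    option_labels: tuple[str, ...] = OPTION_LABELS
    reward_pellets: tuple[int, ...] = (2, 2, 1, 1)
    timeout_seconds: tuple[float, ...] = (444.0, 222.0, 12.0, 6.0)
    penalty_prob: tuple[float, ...] = (0.5, 0.25, 0.25, 0.5)
    #: immediate pellet-unit penalty per option; the canonical table uses the
    #: printed values (-50, -25, -4/3, -2/3) rather than the raw quotients.
    penalty_pellets: tuple[float, ...] = (-50.0, -25.0, -4.0 / 3.0, -2.0 / 3.0)
    episode_seconds: float = 9.0
    session_seconds: float = 3600.0
    pellet_cap: int = 250
    forced_exploration_seconds: float = 600.0
    bin_seconds: float = 600.0
    advantageous_set: frozenset[str] = frozenset({"C", "D"})
    hole_to_option: tuple[int, ...] = (0, 1, 2, 3)

    def __post_init__(self) -> None:
        n = len(self.option_labels)
        for name in ("reward_pellets", "timeout_seconds", "penalty_prob", "penalty_pellets"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have {n} entries")
        if not all(0.0 <= p <= 1.0 for p in self.penalty_prob):
            raise ValueError("penalty_prob entries must lie in [0, 1]")
        if not all(t > 0 for t in self.timeout_seconds):
            raise ValueError("timeout_seconds entries must be > 0")
        if not all(x <= 0 for x in self.penalty_pellets):
            raise ValueError("penalty_pellets entries must be <= 0")
        if not all(r >= 1 for r in self.reward_pellets):
            raise ValueError("reward_pellets entries must be >= 1")
        if sorted(self.hole_to_option) != list(range(n)):
            raise ValueError("hole_to_option must be a bijection on holes")
        adv = self.advantageous_set
        if not adv < set(self.option_labels) or not adv:
            raise ValueError("advantageous_set must be a proper nonempty subset of options")

    # -- derived views ---------------------------------------------------

    @property
    def n_options(self) -> int:
        return len(self.option_labels)

    @property
    def n_bins(self) -> int:
        return int(np.ceil(self.session_seconds / self.bin_seconds))

    @property
    def advantageous_flags(self) -> tuple[bool, ...]:
        """Per-option flag: is this contingency in the advantageous set?"""
        return tuple(lab in self.advantageous_set for lab in self.option_labels)

    @property
    def option_to_hole(self) -> tuple[int, ...]:
        inv = [0] * self.n_options
        for h, o in enumerate(self.hole_to_option):
            inv[o] = h
        return tuple(inv)

    def option_index(self, option: int | str) -> int:
        if isinstance(option, str):
            try:
                return self.option_labels.index(option)
            except ValueError:
                raise ValueError(f"unknown option {option!r}") from None
        if not 0 <= option < self.n_options:
            raise ValueError(f"unknown option index {option}")
        return int(option)

    # -- construction ----------------------------------------------------

    @classmethod
    def default(cls, penalty_values: str = "paper") -> "TaskConfig":
        """The canonical RGT configuration.

        ``penalty_values="paper"`` uses the printed pellet-unit penalties
        (-50, -25, -4/3, -2/3); ``"computed"`` derives them exactly from the
        time-outs via :func:`convert_timeout_to_penalty`.
        """
        if penalty_values == "paper":
            return cls()
        if penalty_values == "computed":
            base = cls()
            pens = tuple(
                convert_timeout_to_penalty(t, base.episode_seconds)
                for t in base.timeout_seconds
            )
            return replace(base, penalty_pellets=pens)
        raise ValueError("penalty_values must be 'paper' or 'computed'")

    # -- JSON ------------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "option_labels": list(self.option_labels),
            "reward_pellets": list(self.reward_pellets),
            "timeout_seconds": list(self.timeout_seconds),
            "penalty_prob": list(self.penalty_prob),
            "penalty_pellets": list(self.penalty_pellets),
            "episode_seconds": self.episode_seconds,
            "session_seconds": self.session_seconds,
            "pellet_cap": self.pellet_cap,
            "forced_exploration_seconds": self.forced_exploration_seconds,
            "bin_seconds": self.bin_seconds,
            "advantageous_set": sorted(self.advantageous_set),
            "hole_to_option": list(self.hole_to_option),
        }
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        kw = dict(d)
        for name in ("option_labels", "reward_pellets", "timeout_seconds",
                     "penalty_prob", "penalty_pellets", "hole_to_option"):
            if name in kw:
                kw[name] = tuple(kw[name])
        if "advantageous_set" in kw:
            kw["advantageous_set"] = frozenset(kw["advantageous_set"])
        return cls(**kw)

    @classmethod
    def from_json(cls, path) -> "TaskConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def packaged_default(cls) -> "TaskConfig":
        """Load the packaged default-configuration fixture."""
        ref = resources.files("rgtlearn.data").joinpath("rgt_task.json")
        return cls.from_dict(json.loads(ref.read_text()))


@dataclass(frozen=True)
class TrialOutcome:
    """Realized outcome of a single choice."""

    option: int
    pellets: int
    penalty_applied: bool
    penalty_pellets: float
    elapsed_seconds: float

    def __post_init__(self) -> None:
        if self.elapsed_seconds <= 0:
            raise ValueError("elapsed_seconds must be > 0")


def sample_outcome(config: TaskConfig, option: int | str, rng: np.random.Generator) -> TrialOutcome:
    """Sample the stochastic outcome of choosing ``option``.

    The reward is delivered deterministically; a time-out penalty follows
    with the option's penalty probability.  The trial consumes
    ``episode_seconds`` per pellet delivered plus the realized time-out.
    """
    o = config.option_index(option)
    penalty = bool(rng.random() < config.penalty_prob[o])
    pellets = config.reward_pellets[o]
    elapsed = config.episode_seconds * pellets
    pen_val = 0.0
    if penalty:
        elapsed += config.timeout_seconds[o]
        pen_val = config.penalty_pellets[o]
    return TrialOutcome(o, pellets, penalty, pen_val, elapsed)


def expected_outcome_value(config: TaskConfig, option: int | str) -> float:
    """Expected pellet-unit value of one trial of ``option``.

    Closed form ``reward + penalty_prob * penalty``; the fixed point that a
    neutral-trait TD learner converges to under repeated sampling.
    """
    o = config.option_index(option)
    return config.reward_pellets[o] + config.penalty_prob[o] * config.penalty_pellets[o]


def make_reversed(config: TaskConfig) -> TaskConfig:
    """Spatially exchange the {A,B} and {C,D} contingencies between holes.

    The contingency tables are untouched; only the hole assignment moves
    (A<->C and B<->D), so an agent whose values are indexed by hole meets
    new outcomes at its preferred locations.  Applying the operation twice
    restores the original assignment.
    """
    new_map = tuple(_REVERSAL_SWAP[o] for o in config.hole_to_option)
    return replace(config, hole_to_option=new_map)
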