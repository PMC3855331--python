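"""Full-session simulation, binned performance profiles, classification.

A session runs the select/sample/update loop under continuous-time
accounting (9 s per pellet consumed plus realized time-outs) until the
one-hour clock or the 250-pellet cap is reached.  Choices are uniform
during the first 10 minutes (forced exploration), softmax afterwards.
Profiles bin trials by start time into six 10-minute blocks; individuals
are classified good/poor/undecided from the percentage of advantageous
choices over the last 20 minutes (>70 / <30 strict bounds).

The reversal condition replays the session on the spatially-exchanged
configuration with the learner's hole-indexed values and penalty history
carried over and both the session clock and the learning-rate decay clock
reset to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd

from .agent import AgentState, TraitParams
from .task import TaskConfig, make_reversed

__all__ = [
    "SessionRecord",
    "PerformanceProfile",
    "UnclassifiableSessionError",
    "run_session",
    "run_reversal_session",
    "bin_profile",
    "classify_rgt",
    "preferred_contingency",
    "flexibility_score",
    "classify_flexibility",
]


class UnclassifiableSessionError(ValueError):
    """Raised when a classification window contains no trials."""


@dataclass
class SessionRecord:
    """Trial-by-trial log of one simulated session."""

    start_seconds: np.ndarray
    hole: np.ndarray
    option: np.ndarray
    pellets: np.ndarray
    penalty_applied: np.ndarray
    penalty_pellets: np.ndarray
    params_used: TraitParams
    config_used: TaskConfig
    final_state: AgentState
    rng_seed: int | None = None

    @property
    def n_trials(self) -> int:
        return len(self.start_seconds)

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-trial table."""
        labels = self.config_used.option_labels
        return pd.DataFrame(
            {
                "seed": self.rng_seed,
                "t_start_s": self.start_seconds,
                "hole": self.hole,
                "option": [labels[o] for o in self.option],
                "pellets": self.pellets,
                "penalty_applied": self.penalty_applied,
                "penalty_pellets": self.penalty_pellets,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class PerformanceProfile:
    """Per-10-min-bin advantageous-choice percentages — the fitting target.

    ``percent[k]`` is the percentage of trials starting in bin ``k`` that
    chose an advantageous contingency (NaN for empty bins);
    ``last20_percent`` pools the trials starting in the final 20 minutes.
    """

    percent: np.ndarray
    counts: np.ndarray
    adv_counts: np.ndarray
    last20_percent: float
    last20_count: int
    rat_id: str | None = None

    @property
    def n_bins(self) -> int:
        return len(self.percent)

    def to_row(self) -> dict:
        row: dict = {"rat_id": self.rat_id}
        for k in range(self.n_bins):
            row[f"x{(k + 1) * 10}"] = self.percent[k]
        for k in range(self.n_bins):
            row[f"n{(k + 1) * 10}"] = int(self.counts[k])
        row["last20"] = self.last20_percent
        return row

    @classmethod
    def from_row(cls, row: dict | pd.Series, n_bins: int = 6) -> "PerformanceProfile":
        pct = np.array([float(row[f"x{(k + 1) * 10}"]) for k in range(n_bins)])
        if all(f"n{(k + 1) * 10}" in row for k in range(n_bins)):
            cnt = np.array([int(row[f"n{(k + 1) * 10}"]) for k in range(n_bins)])
        else:
            cnt = None  # percent-only input; likelihood code falls back
        adv = (
            np.rint(pct * cnt / 100.0).astype(int)
            if cnt is not None
            else np.zeros(n_bins, dtype=int)
        )
        if cnt is None:
            cnt = np.full(n_bins, -1)
        last20 = float(row["last20"]) if "last20" in row else math.nan
        rid = str(row["rat_id"]) if "rat_id" in row else None
        return cls(pct, cnt, adv, last20, -1, rat_id=rid)


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _core(
    config: TaskConfig,
    params: TraitParams,
    rng: np.random.Generator,
    init: AgentState | None = None,
    forced_hole: int | None = None,
    record: bool = True,
):
    """Inner session loop.

    Kept in plain Python with pre-drawn uniform blocks: model fitting
    replays this loop tens of thousands of times, so per-trial overhead
    dominates the whole artifact's runtime.  Exactly two uniforms are
    consumed per trial (action, penalty).

    Returns ``(trials, bin_adv, bin_tot, state)`` where ``trials`` is a
    list of per-trial tuples (or None if ``record`` is false) and
    ``bin_adv``/``bin_tot`` count advantageous/total trials per time bin.
    """
    h2o = config.hole_to_option
    n_opts = config.n_options
    rewards = config.reward_pellets
    pprob = config.penalty_prob
    ppen = config.penalty_pellets
    tout = config.timeout_seconds
    adv = config.advantageous_flags
    episode = config.episode_seconds
    t_end = config.session_seconds
    cap = config.pellet_cap
    t_forced = config.forced_exploration_seconds
    bin_s = config.bin_seconds
    n_bins = config.n_bins

    alpha0 = params.alpha0
    decay = 0.0 if math.isinf(params.tau0) else 1.0 / params.tau0
    omega = params.omega
    rho = params.rho
    inv_eps = 1.0 / params.epsilon

    if init is None:
        q = [0.0] * n_opts
        pn = [0] * n_opts
        pmean = [0.0] * n_opts
        pm2 = [0.0] * n_opts
    else:
        q = [float(v) for v in init.q_values]
        pn = [int(v) for v in init.penalty_n]
        pmean = [float(v) for v in init.penalty_mean]
        pm2 = [float(v) for v in init.penalty_m2]

    t = 0.0
    pellets = 0
    trials: list | None = [] if record else None
    bin_adv = [0] * n_bins
    bin_tot = [0] * n_bins

    exp_ = math.exp
    sqrt_ = math.sqrt
    buf = rng.random(2048)
    bi = 0
    nbuf = len(buf)

    while t < t_end and pellets < cap:
        if bi + 2 > nbuf:
            buf = rng.random(2048)
            bi = 0
        u = buf[bi]
        u2 = buf[bi + 1]
        bi += 2

        if forced_hole is not None:
            h = forced_hole
        elif t < t_forced:
            h = int(u * n_opts)
            if h >= n_opts:
                h = n_opts - 1
        else:
            m = max(q)
            ws = [exp_((qi - m) * inv_eps) for qi in q]
            target = u * sum(ws)
            acc = 0.0
            h = n_opts - 1
            for j in range(n_opts):
                acc += ws[j]
                if target < acc:
                    h = j
                    break

        o = h2o[h]
        pen = u2 < pprob[o]
        r = rewards[o]
        if pen:
            x = ppen[o]
            dur = episode * r + tout[o]
        else:
            x = 0.0
            dur = episode * r

        # Welford update of the hole's penalty statistics, then risk bonus
        n_h = pn[h] + 1
        pn[h] = n_h
        d = x - pmean[h]
        pmean[h] += d / n_h
        pm2[h] += d * (x - pmean[h])
        risk = sqrt_(pm2[h] / n_h) if n_h > 1 else 0.0

        signal = omega * r + x + rho * risk
        alpha = alpha0 * exp_(-t * decay) if decay else alpha0
        q[h] += alpha * (signal - q[h])

        b = int(t / bin_s)
        bin_tot[b] += 1
        if adv[o]:
            bin_adv[b] += 1
        if record:
            trials.append((t, h, o, r, pen, x))

        t += dur
        pellets += r

    state = AgentState(
        q_values=np.array(q),
        penalty_n=np.array(pn, dtype=np.int64),
        penalty_mean=np.array(pmean),
        penalty_m2=np.array(pm2),
        elapsed_seconds=t,
        pellets_earned=pellets,
    )
    return trials, bin_adv, bin_tot, state


def _record_from(trials, state, params, config, seed) -> SessionRecord:
    if trials:
        cols = list(zip(*trials))
    else:
        cols = [[], [], [], [], [], []]
    return SessionRecord(
        start_seconds=np.asarray(cols[0], dtype=float),
        hole=np.asarray(cols[1], dtype=np.int64),
        option=np.asarray(cols[2], dtype=np.int64),
        pellets=np.asarray(cols[3], dtype=np.int64),
        penalty_applied=np.asarray(cols[4], dtype=bool),
        penalty_pellets=np.asarray(cols[5], dtype=float),
        params_used=params,
        config_used=config,
        final_state=state,
        rng_seed=seed,
    )


def run_session(
    config: TaskConfig,
    params: TraitParams,
    rng: np.random.Generator | int | None = None,
    *,
    forced_hole: int | None = None,
) -> SessionRecord:
    """Simulate one full RGT session.

    Parameters
    ----------
    config, params
        Task contingencies and the individual's trait parameters.
    rng
        Seeded generator or integer seed (for reproducibility).
    forced_hole
        Diagnostic override: force every choice to this hole, bypassing
        the policy (used e.g. to drive values to their fixed points).
    """
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = _as_rng(rng)
    trials, _, _, state = _core(config, params, gen, forced_hole=forced_hole)
    return _record_from(trials, state, params, config, seed)


def run_reversal_session(
    config: TaskConfig,
    params: TraitParams,
    carried_state: AgentState,
    rng: np.random.Generator | int | None = None,
) -> SessionRecord:
    """Simulate a reversal session continuing from a completed RGT session.

    The hole-indexed values and penalty statistics persist; the session
    clock and the learning-rate decay clock restart at zero; contingencies
    are met through the spatially-exchanged hole assignment.
    """
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = _as_rng(rng)
    rev_cfg = make_reversed(config)
    trials, _, _, state = _core(rev_cfg, params, gen, init=carried_state)
    return _record_from(trials, state, params, rev_cfg, seed)


def bin_profile(record: SessionRecord) -> PerformanceProfile:
    """Bin a session into 10-minute blocks of % advantageous choices.

    Trials are assigned by start time with half-open bins
    ``[k*600, (k+1)*600)``; empty bins carry NaN percentages.  The last-20
    summary pools trials (it is not the mean of the two bin percentages).
    """
    if record.n_trials == 0:
        raise UnclassifiableSessionError("session contains no trials")
    cfg = record.config_used
    n_bins = cfg.n_bins
    adv_flags = np.array(cfg.advantageous_flags)
    is_adv = adv_flags[record.option]
    b = (record.start_seconds // cfg.bin_seconds).astype(int)
    counts = np.bincount(b, minlength=n_bins)[:n_bins]
    adv_counts = np.bincount(b, weights=is_adv, minlength=n_bins)[:n_bins].astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(counts > 0, 100.0 * adv_counts / np.maximum(counts, 1), np.nan)

    t0 = cfg.session_seconds - 2 * cfg.bin_seconds
    in_last = record.start_seconds >= t0
    n_last = int(in_last.sum())
    last20 = 100.0 * is_adv[in_last].sum() / n_last if n_last else math.nan
    return PerformanceProfile(pct, counts, adv_counts, last20, n_last)


def classify_rgt(profile: PerformanceProfile) -> str:
    """Good (>70), poor (<30) or undecided, from last-20-min performance.

    The bounds are strict: exactly 70% or 30% is undecided.
    """
    x = profile.last20_percent
    if math.isnan(x):
        raise UnclassifiableSessionError("no trials in the final 20 minutes")
    if x > 70.0:
        return "good"
    if x < 30.0:
        return "poor"
    return "undecided"


def preferred_contingency(rgt_record: SessionRecord) -> str:
    """Contingency pair preferred in the last 20 min of the RGT session.

    Returns ``"advantageous"`` when at least half of the last-20 trials
    chose {C, D}, else ``"disadvantageous"``.
    """
    prof = bin_profile(rgt_record)
    if math.isnan(prof.last20_percent):
        raise UnclassifiableSessionError("no trials in the final 20 minutes")
    return "advantageous" if prof.last20_percent >= 50.0 else "disadvantageous"


def flexibility_score(reversal_record: SessionRecord, rgt_preferred: str) -> float:
    """Percentage of last-20-min reversal trials that re-tracked the
    previously preferred contingency at its new location.

    Because contingencies move with the holes in the reversal, choosing
    the preferred pair's new location is the same as choosing that
    contingency; perseverating on the old holes selects the other pair.
    """
    cfg = reversal_record.config_used
    if rgt_preferred == "advantageous":
        flags = np.array(cfg.advantageous_flags)
    elif rgt_preferred == "disadvantageous":
        flags = ~np.array(cfg.advantageous_flags)
    else:
        raise ValueError(f"unknown contingency pair {rgt_preferred!r}")
    t0 = cfg.session_seconds - 2 * cfg.bin_seconds
    in_last = reversal_record.start_seconds >= t0
    n = int(in_last.sum())
    if n == 0:
        raise UnclassifiableSessionError("no reversal trials in the final 20 minutes")
    return 100.0 * flags[reversal_record.option[in_last]].sum() / n


def classify_flexibility(score_percent: float) -> str:
    """Flexible (>60), inflexible (<40) or undecided (40-60)."""
    if score_percent > 60.0:
        return "flexible"
    if score_percent < 40.0:
        return "inflexible"
    return "undecided"
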