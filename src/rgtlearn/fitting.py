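"""Simulation-based maximum-likelihood estimation of trait parameters.

The likelihood of a rat's binned performance profile under a candidate
parameter set is intractable in closed form, so it is estimated by
simulation: the session model is run ``n_runs`` times (50 by default) at
the candidate parameters, the advantageous-choice probability of each
10-minute bin is read off the pooled simulated trials (with Laplace
smoothing, ``(adv + 1) / (total + 2)``), and the observed per-bin
advantageous counts are scored under independent binomial observation
models.

Every likelihood evaluation reuses one fixed set of per-run seeds derived
from the master seed (common random numbers), which makes the objective a
deterministic function of the parameters and lets standard derivative-free
optimisation work: a coarse grid over the free parameters followed by
Nelder-Mead refinement from the best grid point.

Nested model variants switch individual traits off (reward weight pinned
at 1, risk coefficient at 0, decay time constant at infinity); the initial
learning rate and the softmax temperature are always free, so the full
model has five free parameters.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .agent import TraitParams
from .session import PerformanceProfile, _core
from .task import TaskConfig, make_reversed

__all__ = [
    "ModelVariant",
    "VARIANTS",
    "SearchSpec",
    "BinDistribution",
    "FitResult",
    "simulate_bin_distributions",
    "profile_log_likelihood",
    "fit_ml",
    "fit_joint",
]

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class ModelVariant:
    """Which behavioural traits are free in a nested model variant.

    The initial learning rate and the temperature are always estimated, so
    the number of free parameters is 2 plus one per active trait
    (inflexibility contributes the decay time constant).
    """

    use_reward_seeking: bool = True
    use_risk_seeking: bool = True
    use_inflexibility: bool = True

    @property
    def n_free_parameters(self) -> int:
        return 2 + self.use_reward_seeking + self.use_risk_seeking + self.use_inflexibility

    @property
    def name(self) -> str:
        parts = []
        if self.use_reward_seeking:
            parts.append("reward")
        if self.use_risk_seeking:
            parts.append("risk")
        if self.use_inflexibility:
            parts.append("inflex")
        if len(parts) == 3:
            return "full"
        return "+".join(parts) if parts else "base"

    def is_nested_in(self, other: "ModelVariant") -> bool:
        return (
            (not self.use_reward_seeking or other.use_reward_seeking)
            and (not self.use_risk_seeking or other.use_risk_seeking)
            and (not self.use_inflexibility or other.use_inflexibility)
        )

    def free_names(self) -> list[str]:
        names = ["alpha0", "epsilon"]
        if self.use_reward_seeking:
            names.append("omega")
        if self.use_risk_seeking:
            names.append("rho")
        if self.use_inflexibility:
            names.append("tau0")
        return names

    def build_params(self, values: Mapping[str, float]) -> TraitParams:
        """Trait parameters with inactive traits pinned at neutral values."""
        return TraitParams(
            alpha0=values["alpha0"],
            epsilon=values["epsilon"],
            omega=values["omega"] if self.use_reward_seeking else 1.0,
            rho=values["rho"] if self.use_risk_seeking else 0.0,
            tau0=values["tau0"] if self.use_inflexibility else math.inf,
        )


#: Named registry of all nested variants.
VARIANTS: dict[str, ModelVariant] = {
    v.name: v
    for v in (
        ModelVariant(r, s, i)
        for r in (True, False)
        for s in (True, False)
        for i in (True, False)
    )
}

#: Search bounds per parameter (natural scale) and whether the coordinate is
#: searched on a log scale.  tau0 is optimised as a decay rate 1/tau0 so the
#: constant-rate limit sits at the finite boundary 0.
BOUNDS: dict[str, tuple[float, float, bool]] = {
    "alpha0": (0.01, 1.0, True),
    "epsilon": (0.05, 5.0, True),
    "omega": (0.5, 4.0, True),
    "rho": (-1.0, 2.0, False),
    "tau0": (60.0, math.inf, False),
}

DEFAULT_GRID: dict[str, tuple[float, ...]] = {
    "alpha0": (0.02, 0.05, 0.15, 0.4, 0.9),
    "epsilon": (0.1, 0.3, 1.0, 3.0),
    "omega": (0.7, 1.0, 1.5, 2.2, 3.0, 3.8),
    "rho": (-0.5, 0.0, 0.5, 1.0, 1.5, 2.0),
    "tau0": (120.0, 300.0, 900.0, math.inf),
}

#: Safe mid-range starting point always included in the grid stage.
_CENTER = {"alpha0": 0.3, "epsilon": 0.5, "omega": 1.0, "rho": 0.0, "tau0": math.inf}


@dataclass
class SearchSpec:
    """Budget and bounds of the two-stage parameter search."""

    n_runs: int = 50
    grid: Mapping[str, Sequence[float]] | None = None
    max_grid_points: int = 120
    refine_maxfev: int = 60
    assumed_bin_count: int = 30
    bounds: Mapping[str, tuple[float, float, bool]] | None = None

    def grid_for(self, name: str) -> Sequence[float]:
        if self.grid is not None and name in self.grid:
            return tuple(self.grid[name])
        return DEFAULT_GRID[name]

    def bounds_for(self, name: str) -> tuple[float, float, bool]:
        if self.bounds is not None and name in self.bounds:
            return self.bounds[name]
        return BOUNDS[name]


@dataclass
class BinDistribution:
    """Simulated per-bin advantageous-choice probabilities."""

    probs: np.ndarray
    available: np.ndarray
    totals: np.ndarray
    adv_totals: np.ndarray


def _pooled_distribution(adv: np.ndarray, tot: np.ndarray) -> BinDistribution:
    avail = tot > 0
    with np.errstate(invalid="ignore"):
        p = (adv + 1.0) / (tot + 2.0)
    return BinDistribution(p, avail, tot, adv)


def _simulate_counts(
    params: TraitParams,
    config: TaskConfig,
    seeds: Sequence[int],
    with_reversal: bool = False,
) -> tuple[BinDistribution, BinDistribution | None]:
    n_bins = config.n_bins
    adv = np.zeros(n_bins)
    tot = np.zeros(n_bins)
    radv = np.zeros(n_bins)
    rtot = np.zeros(n_bins)
    rev_cfg = make_reversed(config) if with_reversal else None
    for s in seeds:
        rng = np.random.default_rng(int(s))
        _, a, t, state = _core(config, params, rng, record=False)
        adv += a
        tot += t
        if with_reversal:
            _, a2, t2, _ = _core(rev_cfg, params, rng, init=state, record=False)
            radv += a2
            rtot += t2
    rgt = _pooled_distribution(adv, tot)
    rev = _pooled_distribution(radv, rtot) if with_reversal else None
    return rgt, rev


def simulate_bin_distributions(
    params: TraitParams,
    config: TaskConfig,
    n_runs: int = 50,
    rng: np.random.Generator | int | None = None,
    seeds: Sequence[int] | None = None,
    with_reversal: bool = False,
):
    """Estimate per-bin advantageous-choice probabilities by simulation.

    Runs ``n_runs`` sessions, pools trials per bin across runs, and
    returns Laplace-smoothed probabilities ``(adv + 1) / (total + 2)``
    (strictly inside (0, 1)); bins no run ever reached are flagged
    unavailable.  Passing the same ``seeds`` always reproduces the same
    output exactly — the common-random-number contract the optimiser
    relies on.
    """
    if seeds is None:
        if n_runs < 2:
            raise ValueError("n_runs must be >= 2")
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        seeds = gen.integers(0, _MAX_SEED, size=n_runs)
    elif len(seeds) < 2:
        raise ValueError("need at least 2 simulation seeds")
    rgt, rev = _simulate_counts(params, config, seeds, with_reversal=with_reversal)
    return (rgt, rev) if with_reversal else rgt


def profile_log_likelihood(
    profile: PerformanceProfile,
    bin_dist: BinDistribution,
    assumed_bin_count: int = 30,
) -> float:
    """Binomial log-likelihood of an observed profile under simulated
    per-bin probabilities.

    Bins are treated as independent; a bin contributes
    ``log Binom(k_obs | n_obs, p_sim)``.  Bins that are empty in the data
    or unavailable in the simulation are dropped.  Profiles read from
    percent-only tables carry no trial counts; those fall back to an
    assumed per-bin count (default 30) with a warning.
    """
    n_bins = profile.n_bins
    counts = np.asarray(profile.counts, dtype=float)
    if np.any(counts < 0):
        warnings.warn(
            f"profile has no per-bin trial counts; assuming {assumed_bin_count} trials per bin",
            stacklevel=2,
        )
        counts = np.where(~np.isnan(profile.percent), float(assumed_bin_count), 0.0)
        k_obs = np.rint(np.nan_to_num(profile.percent) * counts / 100.0)
    else:
        k_obs = np.asarray(profile.adv_counts, dtype=float)
    use = (counts > 0) & bin_dist.available[:n_bins] & ~np.isnan(profile.percent)
    if not use.any():
        raise ValueError("no usable bins shared between profile and simulation")
    ll = stats.binom.logpmf(k_obs[use], counts[use], bin_dist.probs[:n_bins][use])
    return float(ll.sum())


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    variant: ModelVariant
    params: TraitParams
    log_likelihood: float
    n_observation_bins: int
    n_simulation_runs: int
    optimizer_trace: list = field(default_factory=list)
    eval_seeds: list = field(default_factory=list)

    @property
    def theta_hat(self) -> TraitParams:
        return self.params

    def to_dict(self) -> dict:
        return {
            "variant": {
                "use_reward_seeking": self.variant.use_reward_seeking,
                "use_risk_seeking": self.variant.use_risk_seeking,
                "use_inflexibility": self.variant.use_inflexibility,
            },
            "theta_hat": self.params.to_dict(),
            "log_likelihood": self.log_likelihood,
            "n_observation_bins": self.n_observation_bins,
            "n_simulation_runs": self.n_simulation_runs,
            "eval_seeds": [int(s) for s in self.eval_seeds],
            "n_evaluations": len(self.optimizer_trace),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            variant=ModelVariant(**d["variant"]),
            params=TraitParams.from_dict(d["theta_hat"]),
            log_likelihood=d["log_likelihood"],
            n_observation_bins=d["n_observation_bins"],
            n_simulation_runs=d["n_simulation_runs"],
            eval_seeds=d.get("eval_seeds", []),
        )


def _as_profile_list(profiles) -> list[PerformanceProfile]:
    if isinstance(profiles, PerformanceProfile):
        return [profiles]
    out = list(profiles)
    if not out:
        raise ValueError("need at least one profile")
    return out


def _count_usable_bins(profile: PerformanceProfile) -> int:
    counts = np.asarray(profile.counts, dtype=float)
    if np.any(counts < 0):
        return int((~np.isnan(profile.percent)).sum())
    return int(((counts > 0) & ~np.isnan(profile.percent)).sum())


def _fit(
    rgt_profiles: list[PerformanceProfile],
    rev_profiles: list[PerformanceProfile] | None,
    variant: ModelVariant,
    config: TaskConfig,
    search: SearchSpec,
    rng: np.random.Generator | int | None,
    extra_starts: Sequence[TraitParams] | None = None,
) -> FitResult:
    master = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    eval_seeds = master.integers(0, _MAX_SEED, size=search.n_runs)
    free = variant.free_names()
    with_rev = rev_profiles is not None

    trace: list[tuple[dict, float]] = []

    def log_likelihood(values: Mapping[str, float]) -> float:
        params = variant.build_params(values)
        rgt_dist, rev_dist = _simulate_counts(
            params, config, eval_seeds, with_reversal=with_rev
        )
        ll = sum(
            profile_log_likelihood(p, rgt_dist, search.assumed_bin_count)
            for p in rgt_profiles
        )
        if with_rev:
            ll += sum(
                profile_log_likelihood(p, rev_dist, search.assumed_bin_count)
                for p in rev_profiles
            )
        trace.append((dict(values), ll))
        return ll

    # -- stage 1: coarse grid -------------------------------------------
    axes = [tuple(search.grid_for(name)) for name in free]
    points = [dict(zip(free, combo)) for combo in itertools.product(*axes)]
    if len(points) > search.max_grid_points:
        idx = master.choice(len(points), size=search.max_grid_points, replace=False)
        points = [points[i] for i in sorted(idx)]
    points.append({name: _CENTER[name] for name in free})
    for start in extra_starts or ():
        points.append({name: getattr(start, name) for name in free})

    best_values: dict | None = None
    best_ll = -math.inf
    for values in points:
        ll = log_likelihood(values)
        if math.isfinite(ll) and ll > best_ll:
            best_ll, best_values = ll, dict(values)
    if best_values is None:
        raise RuntimeError("no grid point produced a finite likelihood")

    # -- stage 2: Nelder-Mead refinement --------------------------------
    # Internal coordinates: log10 for log-scaled parameters, the decay rate
    # 1/tau0 for the time constant (so tau0 = inf is the finite boundary 0);
    # values are clipped to bounds inside the objective.
    def to_internal(values: dict) -> np.ndarray:
        u = []
        for name in free:
            lo, hi, is_log = search.bounds_for(name)
            v = values[name]
            if name == "tau0":
                u.append(0.0 if math.isinf(v) else 1.0 / v)
            elif is_log:
                u.append(math.log10(v))
            else:
                u.append(v)
        return np.array(u)

    def from_internal(u: np.ndarray) -> dict:
        values = {}
        for name, ui in zip(free, u):
            lo, hi, is_log = search.bounds_for(name)
            if name == "tau0":
                k = min(max(float(ui), 0.0), 1.0 / lo)
                values[name] = math.inf if k == 0.0 else 1.0 / k
            elif is_log:
                v = 10.0 ** float(ui)
                values[name] = min(max(v, lo), hi)
            else:
                values[name] = min(max(float(ui), lo), hi)
        return values

    if search.refine_maxfev > 0:
        def neg_ll(u: np.ndarray) -> float:
            return -log_likelihood(from_internal(u))

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            optimize.minimize(
                neg_ll,
                to_internal(best_values),
                method="Nelder-Mead",
                options={"maxfev": search.refine_maxfev, "xatol": 1e-3, "fatol": 1e-3},
            )

    # The returned optimum is the best evaluation seen anywhere in the trace.
    best_values, best_ll = max(trace, key=lambda e: e[1] if math.isfinite(e[1]) else -math.inf)
    params = variant.build_params(best_values)

    n_obs = sum(_count_usable_bins(p) for p in rgt_profiles)
    if with_rev:
        n_obs += sum(_count_usable_bins(p) for p in rev_profiles)
    return FitResult(
        variant=variant,
        params=params,
        log_likelihood=float(best_ll),
        n_observation_bins=n_obs,
        n_simulation_runs=search.n_runs,
        optimizer_trace=trace,
        eval_seeds=[int(s) for s in eval_seeds],
    )


def fit_ml(
    profiles,
    variant: ModelVariant | str = "full",
    config: TaskConfig | None = None,
    search: SearchSpec | None = None,
    rng: np.random.Generator | int | None = None,
    extra_starts: Sequence[TraitParams] | None = None,
) -> FitResult:
    """Fit trait parameters to one individual's RGT performance profile(s).

    Two-stage deterministic search (given the master seed): a coarse grid
    over the variant's free parameters — thinned to ``max_grid_points`` by
    random subsampling when the factorial grid is larger — then
    Nelder-Mead refinement from the best grid point, all evaluations
    sharing one set of simulation seeds.
    """
    if isinstance(variant, str):
        variant = VARIANTS[variant]
    config = config or TaskConfig.default()
    search = search or SearchSpec()
    return _fit(_as_profile_list(profiles), None, variant, config, search, rng,
                extra_starts=extra_starts)


def fit_joint(
    rgt_profile,
    reversal_profile,
    variant: ModelVariant | str = "full",
    config: TaskConfig | None = None,
    search: SearchSpec | None = None,
    rng: np.random.Generator | int | None = None,
    extra_starts: Sequence[TraitParams] | None = None,
) -> FitResult:
    """Fit one individual jointly to RGT and reversal profiles.

    The objective adds the reversal-session bin log-likelihoods, with each
    simulated reversal continuing from its paired simulated RGT session
    (values and penalty history carried over, clocks reset).  With no
    reversal profile this reduces exactly to :func:`fit_ml`.
    """
    if isinstance(variant, str):
        variant = VARIANTS[variant]
    config = config or TaskConfig.default()
    search = search or SearchSpec()
    if reversal_profile is None:
        return _fit(_as_profile_list(rgt_profile), None, variant, config, search, rng,
                    extra_starts=extra_starts)
    return _fit(
        _as_profile_list(rgt_profile),
        _as_profile_list(reversal_profile),
        variant,
        config,
        search,
        rng,
        extra_starts=extra_starts,
    )


def fit_variant_family(
    profiles,
    variant_names: Sequence[str] = (
        "base", "reward", "risk", "inflex",
        "reward+risk", "reward+inflex", "risk+inflex", "full",
    ),
    config: TaskConfig | None = None,
    search: SearchSpec | None = None,
    rng_seed: int = 0,
    reversal_profiles=None,
) -> dict[str, FitResult]:
    """Fit a nested family of variants to one individual, simplest first.

    Each fuller variant's grid stage additionally starts from the optima
    of every variant nested within it.  Combined with one master seed per
    individual (so all variants share the same simulation seeds), this
    guarantees the nesting property ``logL(fuller) >= logL(nested)`` that
    the likelihood-ratio test presupposes.
    """
    config = config or TaskConfig.default()
    search = search or SearchSpec()
    results: dict[str, FitResult] = {}
    for name in variant_names:
        variant = VARIANTS[name]
        starts = [
            f.params for v, f in results.items()
            if VARIANTS[v].is_nested_in(variant)
        ]
        if reversal_profiles is None:
            results[name] = fit_ml(profiles, variant, config, search,
                                   rng=rng_seed, extra_starts=starts)
        else:
            results[name] = fit_joint(profiles, reversal_profiles, variant, config,
                                      search, rng=rng_seed, extra_starts=starts)
    return results
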