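"""Model comparison and cohort-profiling statistics.

Nested trait variants are compared with the likelihood-ratio test and the
Bayesian Information Criterion on pooled cohort likelihoods.  Individual
differences are profiled with the field's bespoke statistics: a Monte
Carlo permutation test for correlation significance, a group correlation
over +/-1 median-split score vectors, a sum-of-ranks global index across
the behavioural battery, and median-split trait tables marking which
individuals score high on each trait.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fitting import FitResult
from .session import SessionRecord

__all__ = [
    "bic",
    "lrt",
    "compare_variants",
    "mc_permutation_corr",
    "group_correlation",
    "global_index",
    "median_split_profile",
    "qvalue_summary",
]


def bic(fit: FitResult, n_obs: int | None = None) -> float:
    """Bayesian Information Criterion ``k ln(n) - 2 logL`` (lower better).

    ``n`` is the number of observation bins entering the likelihood
    (taken from the fit when not given).
    """
    if n_obs is None:
        n_obs = fit.n_observation_bins
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    k = fit.variant.n_free_parameters
    return k * np.log(n_obs) - 2.0 * fit.log_likelihood


def lrt(full_fit: FitResult, nested_fit: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested variant against a fuller one.

    Returns ``(statistic, df, p)`` with the statistic referred to a
    chi-square with df = difference in free-parameter counts.  The
    likelihoods here are simulation-based estimates, so the chi-square
    reference is an approximation; negative statistics from simulation
    noise are floored at zero.
    """
    if not nested_fit.variant.is_nested_in(full_fit.variant):
        raise ValueError(
            f"variant {nested_fit.variant.name!r} is not nested in {full_fit.variant.name!r}"
        )
    df = full_fit.variant.n_free_parameters - nested_fit.variant.n_free_parameters
    if df <= 0:
        raise ValueError("models are not properly nested (df must be > 0)")
    stat = max(0.0, 2.0 * (full_fit.log_likelihood - nested_fit.log_likelihood))
    p = float(sps.chi2.sf(stat, df)) if stat > 0 else 1.0
    return stat, df, p


def compare_variants(
    fits_by_variant: Mapping[str, Sequence[FitResult]],
    full_name: str = "full",
) -> pd.DataFrame:
    """Cohort-level comparison table across model variants.

    Per-rat fits are pooled by summing log-likelihoods and observation-bin
    counts; the LRT columns test each variant against the full model.
    """
    if full_name not in fits_by_variant:
        raise ValueError(f"no fits for reference variant {full_name!r}")
    pooled = {}
    for name, fits in fits_by_variant.items():
        fits = list(fits)
        ll = sum(f.log_likelihood for f in fits)
        n_obs = sum(f.n_observation_bins for f in fits)
        k = fits[0].variant.n_free_parameters
        pooled[name] = (fits[0].variant, k, ll, n_obs)

    full_variant, k_full, ll_full, n_full = pooled[full_name]
    rows = []
    for name, (variant, k, ll, n_obs) in pooled.items():
        row = {
            "variant": name,
            "n_free_parameters": k,
            "log_likelihood": ll,
            "n_obs": n_obs,
            "bic": k * np.log(n_obs) - 2.0 * ll,
        }
        if name != full_name and variant.is_nested_in(full_variant):
            stat = max(0.0, 2.0 * (ll_full - ll))
            df = k_full - k
            row["lrt_stat"] = stat
            row["lrt_df"] = df
            row["lrt_p"] = float(sps.chi2.sf(stat, df))
        else:
            row["lrt_stat"] = np.nan
            row["lrt_df"] = np.nan
            row["lrt_p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).sort_values("bic").reset_index(drop=True)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    return float((xc * yc).sum() / denom)


def mc_permutation_corr(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 100_000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Pearson correlation with a two-sided Monte Carlo permutation p-value.

    One vector is randomly permuted ``n_perm`` times to build the null
    distribution of the coefficient; the p-value is
    ``(1 + #{|r*| >= |r|}) / (n_perm + 1)``, which is valid (never zero)
    at any finite number of permutations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-d vectors of length >= 3")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    r = _pearson(x, y)

    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    # permute y in blocks to bound memory at large n_perm
    count = 0
    block = max(1, min(n_perm, 20_000_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        perm = gen.permuted(np.tile(yc, (b, 1)), axis=1)
        r_null = perm @ xc / denom
        count += int((np.abs(r_null) >= abs(r) - 1e-12).sum())
        done += b
    p = (1 + count) / (n_perm + 1)
    return r, float(p)


def median_signs(x: Sequence[float]) -> np.ndarray:
    """Map scores to +1 (at or above the median) / -1 (below)."""
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    signs = np.where(x >= med, 1.0, -1.0)
    if np.ptp(signs) == 0:
        raise ValueError("degenerate median split: all scores on one side")
    return signs


def group_correlation(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 100_000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Correlation of +/-1 median-split score vectors with a permutation p.

    Each vector is reduced to +1 (at or above its own median) / -1
    (below) before correlating, so the statistic asks only whether the
    two measures agree on which individuals are high scorers.
    """
    return mc_permutation_corr(median_signs(x), median_signs(y), n_perm=n_perm, rng=rng)


def _oriented(scores: pd.DataFrame, orientations: Mapping[str, int]) -> pd.DataFrame:
    missing = set(scores.columns) - set(orientations)
    if missing:
        raise ValueError(f"no orientation given for columns {sorted(missing)}")
    bad = [c for c in scores.columns if orientations[c] not in (1, -1)]
    if bad:
        raise ValueError(f"orientations must be +1 or -1, got invalid entries for {bad}")
    return scores * pd.Series({c: float(orientations[c]) for c in scores.columns})


def global_index(
    score_table: pd.DataFrame,
    orientations: Mapping[str, int],
) -> pd.Series:
    """Sum-of-ranks composite index across the behavioural battery.

    Each score column is ranked within the cohort (average ranks on ties),
    oriented so that a higher rank is more poor-decision-maker-like
    (``orientations[col] = +1`` when high raw scores are poor-like, -1
    when low raw scores are), and the ranks are summed per individual.
    Missing cells are ranked among the available values only.  Being
    rank-based, the index is invariant under any strictly increasing
    transform of any single column.
    """
    oriented = _oriented(score_table, orientations)
    ranks = oriented.rank(axis=0, method="average", na_option="keep")
    out = ranks.sum(axis=1, skipna=True)
    out.name = "global_index"
    return out


def median_split_profile(
    cohort_scores: pd.DataFrame,
    orientations: Mapping[str, int],
) -> pd.DataFrame:
    """Median-split trait table: which individuals score high on each trait.

    A mark (True) means the oriented score is on the poor-like side of, or
    exactly at, the cohort median of that trait; ``n_high`` counts marks
    per individual.
    """
    oriented = _oriented(cohort_scores, orientations)
    med = oriented.median(axis=0, skipna=True)
    marks = oriented.ge(med, axis=1)
    marks = marks.where(~oriented.isna(), other=False)
    out = marks.copy()
    out["n_high"] = marks.sum(axis=1)
    return out


def qvalue_summary(
    records_by_group: Mapping[str, Sequence[SessionRecord]],
) -> pd.DataFrame:
    """End-of-session value summary per group (the over-valuation pattern).

    For each individual the final learned values are averaged over the
    holes carrying the disadvantageous pair {A, B} and over those carrying
    the advantageous pair {C, D}; rows give group means with normal-theory
    95% confidence half-widths over individuals.
    """
    rows = []
    for group, records in records_by_group.items():
        records = list(records)
        if not records:
            raise ValueError(f"group {group!r} has no session records")
        dis_means, adv_means = [], []
        for rec in records:
            adv_flags = np.array(rec.config_used.advantageous_flags)
            hole_is_adv = adv_flags[list(rec.config_used.hole_to_option)]
            q = rec.final_state.q_values
            adv_means.append(q[hole_is_adv].mean())
            dis_means.append(q[~hole_is_adv].mean())
        for pair, vals in (("disadvantageous", dis_means), ("advantageous", adv_means)):
            vals = np.asarray(vals)
            sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
            rows.append(
                {
                    "group": group,
                    "pair": pair,
                    "mean_q": vals.mean(),
                    "ci95_halfwidth": 1.96 * sem,
                    "n": len(vals),
                }
            )
    return pd.DataFrame(rows)
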