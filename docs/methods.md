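# Methods

## The task

The Rat Gambling Task (RGT) is a single-session, four-option operant task.
For one hour (or until 250 pellets have been earned) a rat chooses freely
among four nose-poke holes. Two options (A, B) deliver two pellets
immediately but are followed, with probabilities ½ and ¼, by long
time-outs (444 s and 222 s); the other two (C, D) deliver one pellet with
short, rarer time-outs (12 s at ¼ and 6 s at ½). Because a pellet is
obtained and consumed in about δ_episode = 9 s, a time-out of d seconds is
equivalent to forgoing d/9 pellets, which converts the contingency table
to pellet units: penalties of −50, −25, −4/3 and −2/3 for A–D (the
canonical configuration uses these printed values; a `penalty_values=
"computed"` switch derives them exactly as −d/9). On that scale the
advantageous options C and D tie at an expected 2/3 pellet per trial,
against −23 (A) and −4.25 (B).

`task.TaskConfig` encodes the table, the timing constants, the session
caps and the hole→contingency assignment. Time accounting is per pellet
(a two-pellet trial consumes 18 s) plus any realized time-out. The
session may overshoot the 250-pellet cap by one pellet when a two-pellet
trial crosses it; this mirrors delivery granularity. The reversal
condition exchanges the holes carrying {A, B} with those carrying {C, D}
while leaving the contingencies untouched, so a learner whose values are
indexed by physical hole meets new outcomes at its preferred locations.

## The learner

A temporal-difference value learner over the four holes, with three
behavioural traits, each carried by one parameter:

* **Inflexibility** — the learning rate decays exponentially with session
  time, α(t) = α₀·exp(−t/τ₀), with α₀ ∈ (0, 1] and τ₀ in seconds
  (τ₀ = ∞ ⇒ constant rate). The session-time basis (rather than trial
  count) keeps τ₀ commensurate with the time-binned profiles. The
  integral of α over the hour is the global flexibility index.
* **Reward seeking** — delivered pellets enter the learning signal scaled
  by ω ≥ 0 (ω > 1: subjective over-valuation). The penalty term is
  deliberately *not* scaled: penalty sensitivity is treated as shared
  across individuals.
* **Risk seeking** — an additive bonus ρ·σ(a), where σ(a) is the running
  population standard deviation of the penalty values experienced at hole
  a, counting zero-penalty trials (so, asymptotically, σ is the Bernoulli
  spread |penalty|·√(p(1−p)): 25 pellets for A, 25√3/4 ≈ 10.83 for B).
  The statistic is updated with the current trial's penalty before the
  value update, so the present outcome informs the present bonus;
  σ is zero until a hole has been visited twice.

The per-trial update is Q[h] ← Q[h] + α(t)·(ω·r + x + ρ·σ(h) − Q[h]),
with x the realized pellet-unit penalty (0 if none). All values start at
zero. Choices follow a softmax over hole values with temperature ε
(max-shifted for numerical stability; cumulative-inversion sampling, so
exact value ties are resolved by the random draw). During the first
10 minutes choices are uniform — the infinite-temperature limit of the
"high exploration" imposed at session start — after which the softmax
takes over. No temporal discounting is used: trials are treated as
independent episodes.

In a reversal session the hole-indexed values and penalty statistics
persist from the preceding RGT session while both the session clock and
the decay clock restart (a new day, a retrained animal). Carryover is
what lets pre-reversal learning predict reversal behaviour at all.

## Profiles, classification, flexibility

Sessions are summarized as the percentage of advantageous ({C, D})
choices per 10-minute bin (x₁₀…x₆₀), assigning trials by start time with
half-open bins; empty bins are marked missing and dropped from
likelihoods rather than imputed. The last-20-minute summary pools trials
from [2400 s, 3600 s) — it is not the mean of the two bin percentages.
Individuals are good (> 70%), poor (< 30%) or undecided, with strict
bounds. Reversal flexibility is the percentage of last-20-minute reversal
trials that re-track the previously preferred contingency pair at its new
location (flexible > 60, inflexible < 40, undecided otherwise; the 40–60
band is used throughout, although a stricter < 35 bound also appears in
the source literature's results prose).

## Simulation-based maximum likelihood

The likelihood of an observed profile under candidate parameters θ is
estimated by simulation: run the session model n_runs times (default 50),
pool trials per bin across runs, and take the Laplace-smoothed
advantageous probability p_k = (adv_k + 1)/(total_k + 2). The observed
advantageous count in each bin (exact when trial-level logs exist;
rounded from percentages, with an assumed 30 trials per bin and a
warning, when only percentages are available) is then scored under
independent binomial observation models. The smoothing keeps every p_k
inside (0, 1), so no observation has zero likelihood.

Every likelihood evaluation reuses one fixed set of per-run seeds derived
from the master seed (common random numbers), making the objective a
deterministic function of θ. Optimization is a coarse factorial grid over
the variant's free parameters — thinned by random subsampling when larger
than `max_grid_points` — followed by Nelder–Mead refinement in internal
coordinates (log₁₀ for α₀, ε, ω; linear for ρ; the decay *rate* 1/τ₀ for
the time constant, so τ₀ = ∞ is the finite boundary 0), with values
clipped to bounds inside the objective. Search bounds: α₀ ∈ [0.01, 1],
ε ∈ [0.05, 5], ω ∈ [0.5, 4], ρ ∈ [−1, 2], τ₀ ∈ [60 s, ∞].

Nested variants pin inactive traits at their neutral values (ω = 1,
ρ = 0, τ₀ = ∞); α₀ and ε are always free, so the full model has five
free parameters. `fit_variant_family` fits a nested family simplest
first, warm-starting each fuller variant from every nested optimum under
one shared per-individual seed set; this guarantees the monotone
likelihoods the likelihood-ratio test presupposes (with a subsampled
grid alone, a fuller model can otherwise score below a nested one).
Joint RGT+reversal fits sum the two sessions' bin log-likelihoods, each
simulated reversal continuing from its paired simulated RGT session.

Model comparison pools rats by summing log-likelihoods; BIC uses
k·ln(n_obs) − 2·logL with n_obs the number of observation bins entering
the likelihood (6 per session per rat). The LRT statistic 2·ΔlogL is
referred to a χ² with df equal to the parameter-count difference —
an approximation here, since the likelihoods are simulation-based
estimates; negative statistics arising from residual simulation noise
are floored at zero.

## Cohort statistics

The Monte Carlo permutation test reports Pearson's r with a two-sided
p-value (1 + #{|r*| ≥ |r|})/(n_perm + 1), valid at any finite number of
permutations. The group correlation first reduces each vector to ±1 by
its own median (ties count as high, uniformly) and correlates the sign
vectors. The global index ranks each score column within the cohort
(average ranks on ties, oriented so higher rank = more poor-like), sums
ranks per individual, and is therefore invariant under monotone
transforms of any single column; missing cells are ranked among available
values only. Median-split trait tables mark individuals on the poor-like
side of (or at) each trait's cohort median. Final-value summaries average
end-of-session Q over the holes carrying {A, B} and {C, D} per
individual and report group means with normal-theory 95% intervals,
grouping individuals by their *expressed* classification (good/poor), as
the corresponding experimental comparison does.

## The synthetic cohort

No animal data ship with the package; every downstream stage is
exercised on simulated rats with known ground truth. Two archetypes:

| trait | good | poor |
|---|---|---|
| ω | 0.8–1.2 | 2.8–3.8 |
| ρ | −0.3–0.1 | 1.6–2.0 |
| α₀ | 0.3–0.7 | 0.5–0.9 |
| τ₀ (s) | 1800–∞ | 400–1000 |
| ε | 0.3–1.0 | 0.2–0.4 |

τ₀ is sampled uniformly on the decay-rate scale (so ∞ is reachable).
These ranges were calibrated once, before any acceptance measurement was
frozen, so that the archetypes express their phenotypes and remain
separable on the flexibility index, then fixed. Good draws classify good
essentially always. Poor draws classify poor in roughly three quarters to
four fifths of sessions: the poor phenotype requires at least one
disadvantageous option to survive its earliest samples, and a penalty
landing on the very first visit to both A and B (probability ≈ 0.2 under
uniform forced exploration) extinguishes them before the risk bonus can
build — those rats drift good. This ceiling is a property of the
learning dynamics, not of the ranges. Poor-classified rats robustly show
the over-valuation signature (mean final Q{A,B} ≈ 4–6 > Q{C,D} ≈ 2) and
reversal inflexibility (~20% re-tracking), the latter largely independent
of τ₀ because after reversal their previously preferred holes yield
benign advantageous outcomes, leaving no pressure to relocate.

Behavioural-battery measures are stated monotone transforms of the
generating parameters with multiplicative lognormal noise (unit median;
default coefficient of variation 0.3): reward-collection latency
∝ 1/ω, emergence latency and risk-assessment count ∝ exp(−ρ), operant
press count ∝ exp(+ρ), and the flexibility percentage read directly off
the reversal session. These emulate summary scores only; none of the
underlying operant tasks is simulated mechanistically, so tests passing
on this cohort demonstrate internal consistency of the pipeline, not
external validity on animals.

`CohortSpec(match_behavior=True)` redraws each rat until its session
classification matches its archetype; it is used where a study design
calls for behaviourally defined groups (as experimental good/poor cohorts
are, by definition). `gen_heterogeneous_cohort` additionally spreads the
good rats over flexible / undecided / inflexible decay subtypes (roughly
equal thirds, mirroring the spread this task reveals among good
performers); the inflexible-good subtype is what makes the decay constant
identifiable in model-comparison studies.

## Problem sizes and known limitations

Analysis-scale defaults in the test suite: archetype checks use 20 seeded
sessions; model comparison uses 10-rat cohorts with 20 simulation runs
per likelihood evaluation over three master seeds; parameter recovery
uses a 12-rat cohort at 50 runs per evaluation. The acceptance script
simulates 2 × 20 sessions and runs in seconds.

Known limitations, measured on this implementation:

* At the reference poor-archetype point (ω = 2, ρ = 1, α₀ = 0.2,
  τ₀ = 600 s, ε = 1) the mean last-20-minute advantageous share is ≈
  36–44%, not below the 30% poor bound: with wall-clock decay at
  τ₀ = 600 s, learning is nearly frozen soon after the forced
  exploration phase (≈ 7 trials for slow archetypes), before the risk
  statistics can build the bonus that makes {A, B} dominate. The
  asymptotic valuations (A ≈ 4, B ≈ 8.55 at ω = 2, ρ = 1) are real but
  unreached at that point; stronger trait values (ω ≈ 3, ρ ≈ 1.7,
  ε ≈ 0.3) do produce robust poor behaviour (≈ 20%), which is why the
  frozen archetype ranges sit there.
* The reward weight is only weakly identified from binned advantageous
  percentages: ω and ρ trade off (both inflate option B), and low-ε,
  high-α₀ solutions lock onto early winners at many ω values, so
  cohort-level rank recovery of ω is unstable (≈ 0 to 0.6 across search
  budgets). The risk coefficient and the flexibility index recover well
  (rank correlations ≈ 0.7–0.8 with joint RGT+reversal fits).
* The decay constant's unique likelihood contribution at desk scale is
  ≈ 2 log-units over a 10-rat cohort — below the BIC penalty for one
  extra parameter — so reward+risk is typically the best-BIC variant
  even though every single-trait variant is rejected by the LRT at
  p ≪ 0.05. A small constant learning rate mimics a decaying one on
  these horizons.
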