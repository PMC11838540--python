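# Methods

## Reward-schedule model

A patch visit is a realization of a point process started at patch entry
(`t = 0`). The nominal delivery rate is `r(t) = r0 * exp(-t / tau)` with
`r0 = 1/15` pellets/s and `tau = 300` s; each inter-pellet interval is
drawn from `Normal(mu, sigma)` with `sigma = 4` s and `mu` equal to the
reciprocal of the nominal rate. Non-positive draws are resampled until
strictly positive; with `mu >= 15` and `sigma = 4` a non-positive draw
has probability ~9e-5, so the resampling bias is negligible. The rate
resets to `r0` on every patch entry, so every visit draws a fresh
schedule.

Where the "current" rate is evaluated is genuinely ambiguous: the
package defaults to the rate at the moment of the previous delivery
(`rate_at="draw"`), and also offers the self-consistent reading in which
`mu` solves `mu = 1/r(t_prev + mu)` (`rate_at="delivery"`, via the
principal Lambert-W branch). The two differ at second order; both are
exposed because the residence-time optimum is sensitive to fine
generative detail.

The risky schedule is constructed *from* a realized standard schedule:
each delivery is independently omitted with probability 0.5 and the
survivors pay two pellets. Omitted deliveries are kept as zero-pellet
events so the delivery times of the two variants coincide, which makes
the mean-matching and variance identities transparent: conditional on
`N` scheduled deliveries, the risky payout is a sum of `N` independent
`2*Bernoulli(0.5)` variables, so means match and
`Var_risky = Var_standard + E[N]` (law of total variance). Both
identities are verified by Monte-Carlo tests.

## Optimal fixed residence time

A fixed-residency agent stays exactly `T` seconds in every patch of an
1800-s session and pays a reward-free travel delay `d` between patches
(5 or 30 s). The objective is mean total pellets per session; the final
visit harvests only up to the session end, and trailing travel time is
truncated. The optimum is the argmax of mean earnings over the integer
grid 0–300 s (smallest grid value on ties), computed per schedule
variant; the headline optimum per travel time averages the standard and
risky argmaxes and rounds to the nearest second, since the variants are
mean-matched and their argmaxes differ only by simulation noise.

Two estimators are implemented. The default (`method="curve"`) exploits
the fact that visits are independent and only the *mean* earnings enter
the argmax: it estimates the mean cumulative pellet curve `M(t)` from
many independent schedule draws and scores each grid residence as
`sum_k M(min(T, L - k(T+d)))` over visit starts `k(T+d) < L`. This is an
unbiased estimate of mean session earnings, evaluates the whole grid on
common random numbers (stabilizing the argmax), and is orders of
magnitude cheaper than replicating sessions. The literal per-session
estimator (`method="direct"`) is retained and cross-checked against the
curve estimator in the test suite. Standard and risky curves are
evaluated on shared delivery-time draws, mirroring how the risky
schedule is constructed in the task.

Headline sweeps use 400,000 schedule draws per travel condition, at
least the 10,000 replicate sessions times visits-per-session of a
brute-force sweep. The mean-earnings surface has a sawtooth from the
integer number of visits per session, with a secondary ridge (e.g. near
137 s for `d = 30`) within ~0.1 pellet of the maximum; below roughly
200,000 draws the argmax occasionally jumps ridges, above it the optima
are stable to ±1 s across seeds at 90 s (`d = 5`) and 153 s (`d = 30`).

### The MVT oracle, and why the simulated optimum exceeds it

Under continuous deposition at the nominal rate the cumulative gain is
`g(T) = r0*tau*(1 - exp(-T/tau))`, and maximizing the long-run rate
`g(T)/(T+d)` gives the marginal-value-theorem balance
`exp(T*/tau) = 1 + T*/tau + d/tau`, solved by bracketed root-finding
(53.2 s at `d = 5`; 124.9 s at `d = 30`). `fluid_residence_sweep` scores
the fluid gain at the steady-state rate `L * g(T)/(T+d)` rather than
through the finite-session loop: the fluid limit is the
infinite-horizon idealization, and the finite-session bookkeeping adds
a sawtooth that moves the argmax a few seconds off the closed form. With
steady-state scoring the grid argmax recovers the analytic root within
grid resolution, which is exactly the sanity role the oracle plays.

The stochastic optimum sits ~35 s above the fluid root at either travel
time. The mechanism is discreteness: when the agent leaves, the
"fractional pellet" accumulated toward the next delivery is forfeited,
so each visit under-collects the fluid gain by roughly half a pellet on
average. A per-visit cost of 0.5 pellets inserted into the MVT balance
moves the prediction from 53 to ~90 s and from 125 to ~146 s — matching
the simulation. The optimum is therefore *not* expected to equal the
fluid MVT solution, and the oracle is used only for order-of-magnitude
and monotonicity checks.

## Synthetic cohort generator

`generate_design` crosses three binary factors per subject — the
schedule-type counterbalancing label, the side carrying the risky
schedule, and the travel time — each combination repeated twice, giving
16 sessions per subject and 64 for the default 4 subjects, in an
independently shuffled order per subject. By default every session
presents the risky schedule on one side and the standard schedule on the
other (`assignment_rule="within_session"`), since the within-session
risky-vs-standard comparison requires both; a `"uniform"` rule (both
patches share the focal schedule) is available because the exact
semantics of the eight counterbalanced combinations admit either
reading.

Each visit's intended duration is

```
baseline + subject_intercept + travel_effect*[d=30] + schedule_effect*[risky]
         + interaction*[risky & d=30] + visit_slope*visit_number + Normal(0, residual_sd)
```

floored at 1 s; the subject intercept is drawn once per subject from
`Normal(0, subject_sd)`. Pellet earnings come from the schedule module.
Visits alternate sides, consecutive entries are separated by exactly the
travel delay, and a visit still in progress at 1800 s is truncated and
flagged incomplete.

Defaults (seconds): baseline 135, travel +30, schedule −30, interaction
+35, visit slope 1.5, subject SD 20, residual SD 35. These were
calibrated once so that (i) the fitted z-scale interaction and
visit-number coefficients land near 0.37 and 0.09, the magnitudes the
analysis is meant to exercise; (ii) mean durations exceed the optimal
residence time in all four conditions (the overharvesting regime), with
risky patches visited ~30 s less at short travel but about equally at
long travel; and (iii) a cohort yields ~700 visits, comparable to the
task at this scale. The subject SD of 20 s (ICC ≈ 0.2) is typical
rodent-scale heterogeneity and keeps the 4-subject random-intercept
variance estimable.

What the generator does *not* emulate: within-visit movement or position
traces, satiety or consumption time, session accidents (excluded or
duplicated sessions), autocorrelated or heavy-tailed residuals, and any
learning dynamics — the visit-number slope is a fixed linear trend, not
an adaptive process. Passing tests therefore certify the pipeline's
arithmetic and inferential calibration on well-specified Gaussian
behavior, not robustness to real-rat idiosyncrasies.

## Statistical pipeline

Exclusions run in one global pass: in-progress visits are dropped, then
visits whose duration deviates from the pooled mean by more than 2
pooled sample SDs. The statistics are global (not per condition) and are
reported alongside the retained table; passing them back in reapplies
the identical rule, making the filter idempotent by construction.

The mixed model standardizes duration, travel time, and visit number
(sample-SD convention) and codes the risky schedule as 1; it is fit by
REML with statsmodels' MixedLM using its default optimizer, which we
verified against lme4 on identical data (an alternative optimizer choice
was observed to collapse the random-intercept variance to the boundary
and was discarded). Fixed-effect p-values are large-sample Wald; with
several hundred visits they are indistinguishable from residual-df t
tests. A fuller model adding patch side is available
(`include_side=True`); the default model omits it.

Post-hoc comparisons pair visits by (subject, visit number) cells,
averaging durations within a cell on each side of the comparison and
dropping unmatched cells; the pairing keys are an argument because the
exact pairing underlying this style of analysis is rarely reported. The
four comparisons (risky vs standard at each travel time; long vs short
travel within each schedule) form one Holm family. The Holm step-down
rule is implemented directly (sort ascending, multiply the i-th smallest
by `m - i`, running-maximum monotonicity, cap at 1) and property-tested
against the statsmodels implementation.

Overstaying is `duration - T_opt(travel)` with `T_opt` defaulting to
89 s (short) and 147 s (long); per-condition summaries use t-based 95%
confidence intervals on pooled per-visit values, and normalized duration
(`duration / T_opt`) is additionally summarized for the first four
visits to each individual patch (side within session).

### Known selection effects

Two selection effects are inherent to fixed-length sessions and
documented because they shape parameter recovery. First, a visit close
to the session end stays in the data only if it happens to be short, so
the fitted visit-number slope is attenuated ~20% relative to the
generating slope; the recovery suite asserts the three condition effects
(travel, schedule, interaction) recover with < 10% bias and the visit
slope recovers positive but attenuated. Second, the 2-SD trim removes
extreme durations and thereby shrinks fitted condition contrasts by
~10–15%; recovery and null-calibration experiments therefore run the
model on complete visits, while the full pipeline applies the trim as
the task analysis specifies. Raw per-condition correlations between
visit number and duration are similarly suppressed by visit-count
selection (sessions reaching high visit numbers are those with short
visits), so the correlation utility is validated on a steep-slope,
homogeneous-subject cohort where the within-session trend dominates.

## Determinism and numerics

Every stochastic entry point accepts a seed (integer, `SeedSequence`, or
`Generator`); the pipeline spawns named substreams from one master seed
so a change in one stage's random consumption cannot perturb another's.
Same seed, same output, byte-identical. Argmax ties resolve to the
smallest grid residence. Degenerate inputs (zero spread for z-scores or
correlations, empty grids or tables, single-subject model fits) raise
errors naming the violated requirement rather than returning NaNs.
Visit logs round-trip losslessly through CSV (the reader uses
round-trip float parsing); result tables carry the package version and
a configuration digest in a header comment.

## Problem sizes

Default test and acceptance runs use 400,000 schedule draws per sweep,
10,000 replicates for moment checks, and 200 synthetic cohorts per
recovery experiment; these sizes hold the Monte-Carlo error of each
check well below its assertion tolerance.
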