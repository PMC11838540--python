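# patchforage

Simulation and analysis tools for a two-patch, depleting-reward foraging
task of the kind used to study risk-sensitive patch-leaving decisions in
rats. The package is aimed at behavioral ecologists and decision
neuroscientists who want a tested, seed-reproducible implementation of:

* the task's **stochastic reward schedules** — a standard schedule whose
  delivery rate starts at one pellet per 15 s and decays exponentially
  (time constant 300 s), and a mean-matched **risky** variant built by
  omitting half the deliveries and doubling the payout of the rest;
* a **fixed-residency agent simulation** that locates the
  reward-maximizing patch residence time on a 0–300 s grid for 30-minute
  sessions, with a closed-form **marginal value theorem (MVT)** oracle;
* a **synthetic cohort generator** producing visit-level behavioral logs
  under the study's fully counterbalanced design (2 schedule labels × 2
  risky-patch sides × 2 travel times, twice each, per subject) with known
  effect sizes;
* the **statistical pipeline**: in-progress-visit and 2-SD outlier
  exclusion, z-scoring, the mixed-effects residence-duration model,
  Holm–Bonferroni-corrected post-hoc paired tests, earnings summaries,
  and overstaying (observed minus optimal residence).

## The model

While a forager occupies a patch, pellets drop at intervals drawn from
`Normal(mu, sigma)` with `mu = 1 / r(t)`, `r(t) = r0 * exp(-t / tau)`
(`r0 = 1/15` pellets/s, `tau = 300` s, `sigma = 4` s; non-positive draws
are redrawn). The rate resets on every patch entry. Switching patches
costs a reward-free travel delay `d` (5 or 30 s).

Under the continuous-fluid idealization, cumulative gain is
`g(T) = r0 * tau * (1 - exp(-T / tau))`, and the MVT-optimal residence
solves `exp(T*/tau) = 1 + T*/tau + d/tau` (≈ 53 s at `d = 5`, ≈ 125 s at
`d = 30`). The stochastic simulation's optimum is substantially longer
(≈ 90 s and ≈ 153 s): discrete pellets leave, on average, about half a
pellet "in progress" unharvested at departure — an effective per-visit
cost that rewards fewer, longer visits.

Residence durations are analyzed with

```
duration_z ~ travel_z + schedule + visit_number_z + schedule:travel_z + (1 | subject)
```

with the risky schedule coded 1 and continuous variables z-scored.

## Worked example

```python
from patchforage import (RunConfig, run_full_pipeline,
                         mvt_fluid_optimum, optimal_residence_pair)

pair = optimal_residence_pair(5.0, n_schedules=400_000, seed=1)
print(pair.averaged_optimum)                        # 90
print(mvt_fluid_optimum(travel_time=5.0).t_star)    # 53.2

result = run_full_pipeline(RunConfig(master_seed=1))
print(result.fit.coefficients.round(3))
```

prints the simulated optimum (90 s, well above the 53.2-s fluid MVT
solution) and, for a 64-session synthetic cohort (781 visits; 57
in-progress and 24 outlier visits excluded), the fitted model:

```
                   estimate     se  pvalue  ci_low  ci_high
term
intercept             0.215  0.253   0.395  -0.281    0.711
travel_time           0.291  0.042   0.000   0.209    0.372
reward_schedule      -0.327  0.057   0.000  -0.439   -0.214
visit_number          0.091  0.031   0.003   0.031    0.151
schedule_x_travel     0.397  0.057   0.000   0.284    0.509
```

Durations lengthen with travel time and visit number; risky patches get
shorter visits, but less so at long travel (positive interaction) — the
risk-aversion-under-richness pattern the generator encodes. Post-hoc
paired tests confirm it (risky vs standard at short travel: t = −7.73,
Holm-adjusted p ≈ 6e−10; long vs short travel within each schedule both
significant), mean overstay is positive in all four travel × schedule
conditions (e.g. 47.3 s, 95% CI [42.3, 52.4], in short-travel standard
patches), and sessions with the long travel time earn fewer pellets
(66.9 vs 85.5 on average; pooled t = −8.88, df = 62).

The same steps are available from the shell:

```
patchforage find-optimal --travel 5 --schedule both --seed 1
patchforage generate-cohort --subjects 4 --reps 2 --seed 1 --out visits.csv
patchforage analyze --visits visits.csv --out results/
patchforage run-all --seed 1 --out results/
```

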