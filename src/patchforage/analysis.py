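"""Residence-time and overharvesting statistics for visit-level logs.

Pipeline: exclude in-progress visits and 2-SD duration outliers, z-score
the continuous variables, fit the mixed-effects residence-duration
model

    duration ~ travel_time + schedule + visit_number
               + schedule:travel_time + (1 | subject),

then post-hoc paired comparisons with Holm-Bonferroni correction,
session-earnings tests, duration-binned earnings summaries, overstaying
relative to the optimal residence times, and visit-number correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

__all__ = [
    "FilterReport",
    "LMEFit",
    "PostHocResult",
    "OverstayResult",
    "TwoSampleTResult",
    "filter_visits",
    "zscore",
    "fit_residence_model",
    "policy_z_effects",
    "holm_bonferroni",
    "posthoc_paired_tests",
    "earnings_by_duration_bins",
    "compute_overstaying",
    "residence_visit_correlation",
    "earnings_by_travel_test",
]

MODEL_TERMS = (
    "intercept",
    "travel_time",
    "reward_schedule",
    "visit_number",
    "schedule_x_travel",
)

#: Optimal fixed residence times (seconds) used for overstaying, by
#: travel condition; determined by the fixed-residency sweep.
OPTIMAL_SHORT = 89.0
OPTIMAL_LONG = 147.0


# ---------------------------------------------------------------------------
# filtering and scaling


@dataclass(frozen=True)
class FilterReport:
    """Exclusion accounting for one pass of :func:`filter_visits`."""

    n_input: int
    n_incomplete: int
    n_outlier: int
    n_retained: int
    duration_mean: float
    duration_sd: float
    sd_threshold: float


def filter_visits(
    visits: pd.DataFrame,
    sd_threshold: float = 2.0,
    stats: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the study's exclusion rules to a visit log.

    In-progress (incomplete) visits are dropped first; then any visit
    whose duration deviates from the pooled mean by more than
    ``sd_threshold`` pooled sample standard deviations is excluded.
    Statistics are global (one pass over all sessions and conditions).
    Pass ``stats=(mean, sd)`` to reuse statistics from a previous pass,
    which makes the rule idempotent by construction.
    """
    required = {"duration", "complete"}
    missing = required - set(visits.columns)
    if missing:
        raise ValueError(f"visit table missing column(s): {sorted(missing)}")
    if len(visits) == 0:
        report = FilterReport(0, 0, 0, 0, float("nan"), float("nan"), sd_threshold)
        return visits.copy(), report
    complete = visits[visits["complete"].astype(bool)]
    n_incomplete = len(visits) - len(complete)
    durations = complete["duration"].to_numpy(dtype=float)
    if stats is None:
        mean = float(durations.mean()) if durations.size else float("nan")
        sd = float(durations.std(ddof=1)) if durations.size > 1 else 0.0
    else:
        mean, sd = float(stats[0]), float(stats[1])
    if durations.size and sd > 0:
        keep = np.abs(durations - mean) <= sd_threshold * sd
    else:
        keep = np.ones(len(complete), dtype=bool)
    retained = complete[keep]
    report = FilterReport(
        n_input=len(visits),
        n_incomplete=n_incomplete,
        n_outlier=int((~keep).sum()),
        n_retained=len(retained),
        duration_mean=mean,
        duration_sd=sd,
        sd_threshold=sd_threshold,
    )
    return retained.reset_index(drop=True), report


def zscore(values) -> np.ndarray:
    """Standardize to mean 0 and unit sample standard deviation (ddof=1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("zscore requires at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zscore is undefined for zero-spread input")
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# mixed-effects model


@dataclass(frozen=True)
class LMEFit:
    """Fitted residence-duration mixed model.

    ``coefficients`` is indexed by term with columns
    ``estimate, se, pvalue, ci_low, ci_high``.
    """

    coefficients: pd.DataFrame
    random_intercept_sd: float
    residual_sd: float
    n_obs: int
    n_subjects: int
    converged: bool
    standardized: bool

    def __getitem__(self, term: str) -> pd.Series:
        return self.coefficients.loc[term]


def fit_residence_model(
    visits: pd.DataFrame,
    standardize: bool = True,
    include_side: bool = False,
) -> LMEFit:
    """Fit the mixed-effects model of patch residence duration.

    Fixed effects: travel time and visit number (continuous, z-scored
    when ``standardize``), reward schedule (categorical, risky = 1), and
    the schedule-by-travel interaction; a per-subject random intercept
    absorbs the repeated-measures structure.  The dependent variable is
    z-scored alongside the continuous predictors so coefficient
    magnitudes are comparable.  ``include_side`` adds the patch side as
    a categorical covariate (the fuller model; it is excluded from the
    default model).
    """
    needed = {"duration", "travel_time", "schedule", "visit_number", "subject_id"}
    missing = needed - set(visits.columns)
    if missing:
        raise ValueError(f"visit table missing column(s): {sorted(missing)}")
    n_subjects = visits["subject_id"].nunique()
    if n_subjects < 2:
        raise ValueError(
            "the per-subject random intercept requires at least 2 subjects"
        )
    for col, label in (("schedule", "reward schedule"), ("travel_time", "travel time")):
        if visits[col].nunique() < 2:
            raise ValueError(f"both levels of {label} must be present")
    df = pd.DataFrame(
        {
            "subject": visits["subject_id"].to_numpy(),
            "schedule": (visits["schedule"] == "risky").astype(float).to_numpy(),
        }
    )
    if standardize:
        df["dur"] = zscore(visits["duration"])
        df["travel"] = zscore(visits["travel_time"])
        df["visit"] = zscore(visits["visit_number"])
    else:
        df["dur"] = visits["duration"].to_numpy(dtype=float)
        df["travel"] = visits["travel_time"].to_numpy(dtype=float)
        df["visit"] = visits["visit_number"].to_numpy(dtype=float)
    formula = "dur ~ travel + schedule + visit + schedule:travel"
    if include_side:
        df["side"] = visits["side"].to_numpy()
        formula += " + C(side)"
    model = smf.mixedlm(formula, df, groups=df["subject"])
    fit = model.fit(reml=True)
    rename = {
        "Intercept": "intercept",
        "travel": "travel_time",
        "schedule": "reward_schedule",
        "visit": "visit_number",
        "schedule:travel": "schedule_x_travel",
    }
    fe_names = [n for n in fit.fe_params.index]
    ci = fit.conf_int()
    rows = []
    for name in fe_names:
        term = rename.get(name, name)
        rows.append(
            {
                "term": term,
                "estimate": float(fit.fe_params[name]),
                "se": float(fit.bse[name]),
                "pvalue": float(fit.pvalues[name]),
                "ci_low": float(ci.loc[name, 0]),
                "ci_high": float(ci.loc[name, 1]),
            }
        )
    coefficients = pd.DataFrame(rows).set_index("term")
    return LMEFit(
        coefficients=coefficients,
        random_intercept_sd=float(np.sqrt(fit.cov_re.iloc[0, 0])),
        residual_sd=float(np.sqrt(fit.scale)),
        n_obs=int(fit.nobs),
        n_subjects=int(n_subjects),
        converged=bool(fit.converged),
        standardized=standardize,
    )


def policy_z_effects(policy, visits: pd.DataFrame) -> dict[str, float]:
    """Expected z-scale model coefficients implied by a generative policy.

    The generator specifies effects in seconds; the standardized model
    divides the outcome by the realized duration SD and scales each
    continuous predictor by its realized SD.  With two travel levels 25 s
    apart, the schedule-by-travel interaction coefficient is

        interaction_seconds * sd(travel) / (25 * sd(duration)),

    and similarly for the other terms.  Useful for parameter-recovery
    checks on synthetic cohorts.
    """
    sd_y = float(np.std(visits["duration"], ddof=1))
    sd_travel = float(np.std(visits["travel_time"], ddof=1))
    sd_visit = float(np.std(visits["visit_number"], ddof=1))
    tmin = float(visits["travel_time"].min())
    travel_span = float(visits["travel_time"].max() - tmin)
    # the schedule main effect is evaluated at the mean travel time
    # (z-travel = 0), so the interaction contributes in proportion to the
    # fraction of the travel span above the short level
    frac_long = (float(visits["travel_time"].mean()) - tmin) / travel_span
    return {
        "travel_time": policy.travel_effect * sd_travel / (travel_span * sd_y),
        "reward_schedule": (policy.schedule_effect + policy.interaction * frac_long)
        / sd_y,
        "visit_number": policy.visit_slope * sd_visit / sd_y,
        "schedule_x_travel": policy.interaction * sd_travel / (travel_span * sd_y),
    }


# ---------------------------------------------------------------------------
# post-hoc comparisons


def holm_bonferroni(p_values) -> np.ndarray:
    """Step-down Holm adjustment of a p-value family.

    Sort ascending, multiply the i-th smallest (0-based) by ``m - i``,
    enforce monotonicity by running maximum, cap at 1, and return in
    the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    m = p.size
    adj = p[order] * (m - np.arange(m))
    adj = np.minimum(np.maximum.accumulate(adj), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


@dataclass(frozen=True)
class PostHocResult:
    comparison: str
    t_statistic: float
    df: int
    n_pairs: int
    mean_difference: float
    p_raw: float
    p_adjusted: float = float("nan")


def _paired_cells(
    visits: pd.DataFrame, split_col: str, level_a, level_b, keys
) -> tuple[np.ndarray, np.ndarray]:
    cells = (
        visits.groupby([*keys, split_col], observed=True)["duration"]
        .mean()
        .unstack(split_col)
    )
    for level in (level_a, level_b):
        if level not in cells.columns:
            raise ValueError(f"no visits for condition {split_col}={level!r}")
    cells = cells.dropna(subset=[level_a, level_b])
    return cells[level_a].to_numpy(), cells[level_b].to_numpy()


def posthoc_paired_tests(
    visits: pd.DataFrame,
    pairing: tuple[str, ...] = ("subject_id", "visit_number"),
) -> list[PostHocResult]:
    """The four paired comparisons of the residence-duration analysis.

    Risky vs standard at each travel time, and long vs short travel
    within each schedule.  Visits are paired by averaging durations
    within ``pairing`` cells (default: subject and visit number, pooling
    sessions) on each side of the comparison; cells missing either side
    are dropped.  The four p-values are Holm-adjusted as one family.
    """
    travels = sorted(visits["travel_time"].unique())
    if len(travels) != 2:
        raise ValueError("expected exactly two travel-time levels")
    short, long_ = travels
    specs = [
        ("risky_vs_standard_short_travel", visits["travel_time"] == short,
         "schedule", "risky", "standard"),
        ("risky_vs_standard_long_travel", visits["travel_time"] == long_,
         "schedule", "risky", "standard"),
        ("long_vs_short_travel_standard", visits["schedule"] == "standard",
         "travel_time", long_, short),
        ("long_vs_short_travel_risky", visits["schedule"] == "risky",
         "travel_time", long_, short),
    ]
    partial: list[PostHocResult] = []
    for name, mask, split_col, a, b in specs:
        sub = visits[mask]
        if len(sub) == 0:
            raise ValueError(f"no visits available for comparison {name!r}")
        x, y = _paired_cells(sub, split_col, a, b, list(pairing))
        if x.size < 2:
            raise ValueError(f"fewer than 2 pairs for comparison {name!r}")
        diff = x - y
        if np.allclose(diff.std(ddof=1), 0) and np.allclose(diff.mean(), 0):
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(x, y)
        partial.append(
            PostHocResult(
                comparison=name,
                t_statistic=float(t),
                df=int(x.size - 1),
                n_pairs=int(x.size),
                mean_difference=float(diff.mean()),
                p_raw=float(p),
            )
        )
    adjusted = holm_bonferroni([r.p_raw for r in partial])
    return [
        PostHocResult(
            comparison=r.comparison,
            t_statistic=r.t_statistic,
            df=r.df,
            n_pairs=r.n_pairs,
            mean_difference=r.mean_difference,
            p_raw=r.p_raw,
            p_adjusted=float(p_adj),
        )
        for r, p_adj in zip(partial, adjusted)
    ]


# ---------------------------------------------------------------------------
# earnings summaries


def earnings_by_duration_bins(visits: pd.DataFrame, n_bins: int = 6) -> pd.DataFrame:
    """Mean and SD of pellet earnings within equal-width duration bins.

    Bins are half-open ``[low, high)`` over the pooled duration range,
    with the last bin closed; summaries are computed per bin and
    schedule.  Bins holding fewer than 2 visits report SD 0 and are
    flagged.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be at least 1")
    cols = ["bin_index", "bin_low", "bin_high", "schedule",
            "n", "mean_pellets", "sd_pellets", "flagged"]
    if len(visits) == 0:
        return pd.DataFrame(columns=cols)
    dur = visits["duration"].to_numpy(dtype=float)
    edges = np.linspace(dur.min(), dur.max(), n_bins + 1)
    idx = np.digitize(dur, edges[1:-1], right=False)  # 0..n_bins-1, last closed
    rows = []
    for b in range(n_bins):
        in_bin = visits[idx == b]
        for schedule, grp in in_bin.groupby("schedule", observed=True):
            n = len(grp)
            rows.append(
                {
                    "bin_index": b,
                    "bin_low": float(edges[b]),
                    "bin_high": float(edges[b + 1]),
                    "schedule": schedule,
                    "n": n,
                    "mean_pellets": float(grp["pellets"].mean()),
                    "sd_pellets": float(grp["pellets"].std(ddof=1)) if n >= 2 else 0.0,
                    "flagged": n < 2,
                }
            )
    return pd.DataFrame(rows, columns=cols)


@dataclass(frozen=True)
class TwoSampleTResult:
    t_statistic: float
    df: int
    pvalue: float
    mean_short: float
    mean_long: float
    mean_difference: float  # long - short
    n_short: int
    n_long: int


def earnings_by_travel_test(visits: pd.DataFrame) -> TwoSampleTResult:
    """Pooled-variance two-sample t-test on per-session pellet totals.

    Sessions are grouped by travel time (short vs long); the statistic
    is oriented as long minus short, so a long-travel earnings deficit
    yields a negative mean difference.
    """
    travels = sorted(visits["travel_time"].unique())
    if len(travels) != 2:
        raise ValueError("expected exactly two travel-time levels")
    totals = (
        visits.groupby("session_id", observed=True)
        .agg(travel_time=("travel_time", "first"), pellets=("pellets", "sum"))
    )
    short = totals.loc[totals["travel_time"] == travels[0], "pellets"].to_numpy(float)
    long_ = totals.loc[totals["travel_time"] == travels[1], "pellets"].to_numpy(float)
    if short.size < 2 or long_.size < 2:
        raise ValueError("each travel-time group needs at least 2 sessions")
    if np.allclose(short.std(ddof=1), 0) and np.allclose(long_.std(ddof=1), 0) \
            and np.isclose(short.mean(), long_.mean()):
        t, p = 0.0, 1.0
    else:
        t, p = sps.ttest_ind(long_, short, equal_var=True)
    return TwoSampleTResult(
        t_statistic=float(t),
        df=int(short.size + long_.size - 2),
        pvalue=float(p),
        mean_short=float(short.mean()),
        mean_long=float(long_.mean()),
        mean_difference=float(long_.mean() - short.mean()),
        n_short=int(short.size),
        n_long=int(long_.size),
    )


# ---------------------------------------------------------------------------
# overstaying


@dataclass(frozen=True)
class OverstayResult:
    """Per-visit overstay records plus condition and visit-number summaries.

    ``records`` adds ``overstay`` (observed minus optimal, seconds) and
    ``normalized_duration`` (observed / optimal) per visit;
    ``condition_summary`` holds the mean overstay and a t-based 95%
    confidence interval per (travel x schedule) condition;
    ``by_patch_visit`` holds mean normalized duration for the first four
    visits to a patch, per condition.
    """

    records: pd.DataFrame
    condition_summary: pd.DataFrame
    by_patch_visit: pd.DataFrame
    optimal_short: float
    optimal_long: float


def compute_overstaying(
    visits: pd.DataFrame,
    optimal_short: float = OPTIMAL_SHORT,
    optimal_long: float = OPTIMAL_LONG,
) -> OverstayResult:
    """Overstaying relative to the optimal residence time per condition."""
    if not (optimal_short > 0 and optimal_long > 0):
        raise ValueError("optimal residence times must be positive")
    travels = sorted(visits["travel_time"].unique())
    if len(travels) > 2:
        raise ValueError(f"unknown travel-time labels: {travels}")
    optimal_map = {}
    if travels:
        optimal_map[travels[0]] = optimal_short
    if len(travels) == 2:
        optimal_map[travels[1]] = optimal_long
    records = visits.copy()
    optimal = records["travel_time"].map(optimal_map).to_numpy(dtype=float)
    records["optimal_residence"] = optimal
    records["overstay"] = records["duration"] - optimal
    records["normalized_duration"] = records["duration"] / optimal
    # ordinal visit index per individual patch (side within session)
    records["patch_visit"] = (
        records.groupby(["session_id", "side"], observed=True).cumcount() + 1
    )
    cond_rows = []
    for (travel, schedule), grp in records.groupby(
        ["travel_time", "schedule"], observed=True
    ):
        x = grp["overstay"].to_numpy(dtype=float)
        mean = float(x.mean())
        if x.size > 1 and x.std(ddof=1) > 0:
            lo, hi = sps.t.interval(
                0.95, x.size - 1, loc=mean, scale=sps.sem(x)
            )
        else:
            lo = hi = mean
        cond_rows.append(
            {
                "travel_time": travel,
                "schedule": schedule,
                "n": int(x.size),
                "mean_overstay": mean,
                "ci_low": float(lo),
                "ci_high": float(hi),
                "mean_normalized": float(grp["normalized_duration"].mean()),
            }
        )
    by_visit = (
        records[records["patch_visit"] <= 4]
        .groupby(["travel_time", "schedule", "patch_visit"], observed=True)[
            "normalized_duration"
        ]
        .agg(["mean", "count"])
        .rename(columns={"mean": "mean_normalized", "count": "n"})
        .reset_index()
    )
    return OverstayResult(
        records=records,
        condition_summary=pd.DataFrame(cond_rows),
        by_patch_visit=by_visit,
        optimal_short=optimal_short,
        optimal_long=optimal_long,
    )


def residence_visit_correlation(visits: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of visit number and duration per condition."""
    rows = []
    for (travel, schedule), grp in visits.groupby(
        ["travel_time", "schedule"], observed=True
    ):
        if len(grp) < 3:
            raise ValueError(
                f"need at least 3 visits for travel={travel}, schedule={schedule}"
            )
        x = grp["visit_number"].to_numpy(dtype=float)
        y = grp["duration"].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            raise ValueError(
                "correlation undefined for zero-variance input "
                f"(travel={travel}, schedule={schedule})"
            )
        r, p = sps.pearsonr(x, y)
        rows.append(
            {
                "travel_time": travel,
                "schedule": schedule,
                "n": len(grp),
                "r": float(r),
                "pvalue": float(p),
            }
        )
    return pd.DataFrame(rows)
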