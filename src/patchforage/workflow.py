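"""Configuration, visit-log round-tripping, and the end-to-end pipeline.

The full pipeline is a pure function of a configuration and a master
seed: generate the counterbalanced cohort, filter visits, fit the
mixed model, run the post-hoc family, and summarize earnings and
overstaying.  Every output file carries the package version and a
digest of the fully resolved configuration in a header comment.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import (
    LMEFit,
    OverstayResult,
    compute_overstaying,
    earnings_by_duration_bins,
    earnings_by_travel_test,
    filter_visits,
    fit_residence_model,
    posthoc_paired_tests,
    residence_visit_correlation,
)
from .cohort import VISIT_COLUMNS, PolicyParams, generate_design, simulate_cohort
from .schedule import ScheduleParams

__all__ = [
    "ConfigError",
    "SchemaError",
    "PipelineError",
    "RunConfig",
    "DesignConfig",
    "SweepConfig",
    "AnalysisConfig",
    "load_config",
    "read_visit_log",
    "write_visit_log",
    "run_full_pipeline",
    "PipelineResult",
]

logger = logging.getLogger("patchforage")


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


class SchemaError(ValueError):
    """A visit-log table violates the expected schema."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class DesignConfig:
    n_subjects: int = 4
    reps_per_combo: int = 2
    assignment_rule: str = "within_session"

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.reps_per_combo < 1:
            raise ConfigError("n_subjects and reps_per_combo must be positive")


@dataclass(frozen=True)
class SweepConfig:
    grid_max: int = 300
    n_reps: int = 10_000
    session_length: float = 1800.0
    travel_times: tuple[float, float] = (5.0, 30.0)

    def __post_init__(self) -> None:
        if self.grid_max < 1 or self.n_reps < 1 or self.session_length <= 0:
            raise ConfigError("sweep parameters must be positive")


@dataclass(frozen=True)
class AnalysisConfig:
    sd_threshold: float = 2.0
    optimal_short: float = 89.0
    optimal_long: float = 147.0
    pairing: tuple[str, ...] = ("subject_id", "visit_number")
    n_bins: int = 6

    def __post_init__(self) -> None:
        if self.sd_threshold <= 0:
            raise ConfigError("sd_threshold must be positive")
        if self.optimal_short <= 0 or self.optimal_long <= 0:
            raise ConfigError("optimal residence times must be positive")


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved run configuration; every field has a documented
    default matching the study's task parameters."""

    master_seed: int = 0
    schedule: ScheduleParams = field(default_factory=ScheduleParams)
    policy: PolicyParams = field(default_factory=PolicyParams)
    design: DesignConfig = field(default_factory=DesignConfig)
    sweep: SweepConfig = field(default_factory=SweepConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def digest(self) -> str:
        """Short stable hash of the resolved configuration."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


_SECTIONS = {
    "schedule": ScheduleParams,
    "policy": PolicyParams,
    "design": DesignConfig,
    "sweep": SweepConfig,
    "analysis": AnalysisConfig,
}


def _build_section(cls, values: dict, section: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - fields
    if unknown:
        raise ConfigError(f"unknown key(s) in '{section}': {sorted(unknown)}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name not in values:
            continue
        v = values[f.name]
        try:
            if f.type in ("int",):
                if isinstance(v, float) and not v.is_integer():
                    raise TypeError
                coerced[f.name] = int(v)
            elif f.type in ("float",):
                coerced[f.name] = float(v)
            elif isinstance(v, list):
                coerced[f.name] = tuple(v)
            else:
                coerced[f.name] = v
        except (TypeError, ValueError) as exc:
            raise ConfigError(
                f"bad value for '{section}.{f.name}': {v!r}"
            ) from exc
    try:
        return cls(**coerced)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid '{section}' configuration: {exc}") from exc


def load_config(path) -> RunConfig:
    """Read a YAML configuration, merging file values over defaults.

    Unknown keys are rejected; the fully resolved configuration is
    echoed to the run log at INFO level.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    raw = {} if raw is None else raw
    if not isinstance(raw, dict):
        raise ConfigError("configuration file must contain a mapping")
    unknown = set(raw) - set(_SECTIONS) - {"master_seed"}
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {}
    if "master_seed" in raw:
        try:
            kwargs["master_seed"] = int(raw["master_seed"])
        except (TypeError, ValueError) as exc:
            raise ConfigError("master_seed must be an integer") from exc
    for name, cls in _SECTIONS.items():
        if name in raw:
            if not isinstance(raw[name], dict):
                raise ConfigError(f"section '{name}' must be a mapping")
            kwargs[name] = _build_section(cls, raw[name], name)
    config = RunConfig(**kwargs)
    logger.info("resolved config (digest %s): %s", config.digest(),
                dataclasses.asdict(config))
    return config


# ---------------------------------------------------------------------------
# visit-log round trip

_NUMERIC_COLUMNS = [
    "travel_time", "visit_number", "entry_time", "exit_time", "duration", "pellets",
]


def _file_header(config: RunConfig | None = None) -> str:
    digest = config.digest() if config is not None else "none"
    return f"# patchforage v{__version__} config_digest={digest}\n"


def write_visit_log(table: pd.DataFrame, path, config: RunConfig | None = None) -> None:
    """Write a visit log as comma-delimited UTF-8 text with a header row."""
    missing = [c for c in VISIT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_file_header(config))
        table[VISIT_COLUMNS].to_csv(fh, index=False)


def read_visit_log(path) -> pd.DataFrame:
    """Read and validate a visit log written by :func:`write_visit_log`.

    Schema violations are reported with the offending column and, for
    value-level problems, the 0-based data row index.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in VISIT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    for col in _NUMERIC_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise SchemaError(
                f"unparseable numeric in column '{col}' at row(s) "
                f"{df.index[bad].tolist()}"
            )
        df[col] = coerced
    if df["complete"].dtype != bool:
        df["complete"] = df["complete"].astype(str).str.lower().map(
            {"true": True, "false": False}
        )
        if df["complete"].isna().any():
            raise SchemaError("column 'complete' must be boolean")
    bad_rows = df.index[df["exit_time"] <= df["entry_time"]].tolist()
    if bad_rows:
        raise SchemaError(f"exit_time <= entry_time at row(s) {bad_rows}")
    df["visit_number"] = df["visit_number"].astype(int)
    df["pellets"] = df["pellets"].astype(int)
    return df


# ---------------------------------------------------------------------------
# full pipeline


@dataclass(frozen=True)
class PipelineResult:
    config: RunConfig
    visits: pd.DataFrame
    retained: pd.DataFrame
    filter_report: object
    fit: LMEFit
    posthoc: list
    overstay: OverstayResult
    bins: pd.DataFrame
    correlations: pd.DataFrame
    travel_test: object
    summary: dict


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc

    return wrap


def run_full_pipeline(config: RunConfig = RunConfig(), out_dir=None) -> PipelineResult:
    """Execute cohort generation through overstay summaries with one seed tree.

    The master seed spawns named substreams (design, cohort) so a change
    in one stage's random consumption cannot perturb the others.  If
    ``out_dir`` is given, the visit log, all result tables, and a
    key-value run summary are written there.
    """
    root = np.random.SeedSequence(config.master_seed)
    design_seed, cohort_seed = root.spawn(2)

    designs = _stage("design")(
        generate_design,
        config.design.n_subjects,
        config.design.reps_per_combo,
        seed=design_seed,
        assignment_rule=config.design.assignment_rule,
    )
    logger.info("design: %d sessions", len(designs))
    visits = _stage("cohort")(
        simulate_cohort, designs, config.policy, config.schedule, seed=cohort_seed
    )
    logger.info("cohort: %d visits", len(visits))
    retained, report = _stage("filter")(
        filter_visits, visits, config.analysis.sd_threshold
    )
    logger.info("filter: retained %d of %d visits", report.n_retained, report.n_input)
    fit = _stage("model")(fit_residence_model, retained)
    posthoc = _stage("posthoc")(
        posthoc_paired_tests, retained, pairing=config.analysis.pairing
    )
    overstay = _stage("overstay")(
        compute_overstaying,
        retained,
        config.analysis.optimal_short,
        config.analysis.optimal_long,
    )
    bins = _stage("bins")(earnings_by_duration_bins, retained, config.analysis.n_bins)
    correlations = _stage("correlations")(residence_visit_correlation, retained)
    travel_test = _stage("earnings")(earnings_by_travel_test, retained)

    summary = {
        "n_sessions": int(visits["session_id"].nunique()),
        "n_visits": int(report.n_input),
        "n_retained": int(report.n_retained),
        "n_incomplete": int(report.n_incomplete),
        "n_outlier": int(report.n_outlier),
        "interaction_estimate": float(fit["schedule_x_travel"]["estimate"]),
        "interaction_pvalue": float(fit["schedule_x_travel"]["pvalue"]),
        "visit_number_estimate": float(fit["visit_number"]["estimate"]),
        "random_intercept_sd": float(fit.random_intercept_sd),
        "earnings_t": float(travel_test.t_statistic),
        "earnings_p": float(travel_test.pvalue),
        "mean_pellets_short": float(travel_test.mean_short),
        "mean_pellets_long": float(travel_test.mean_long),
    }
    for _, row in overstay.condition_summary.iterrows():
        key = f"overstay_travel{row['travel_time']:g}_{row['schedule']}"
        summary[key] = float(row["mean_overstay"])

    result = PipelineResult(
        config=config,
        visits=visits,
        retained=retained,
        filter_report=report,
        fit=fit,
        posthoc=posthoc,
        overstay=overstay,
        bins=bins,
        correlations=correlations,
        travel_test=travel_test,
        summary=summary,
    )
    if out_dir is not None:
        _write_bundle(result, Path(out_dir))
    return result


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_file_header(config))
        df.to_csv(fh, index=False)


def _write_bundle(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    write_visit_log(result.visits, out_dir / "visits.csv", cfg)
    _write_table(
        result.fit.coefficients.reset_index(), out_dir / "model_coefficients.csv", cfg
    )
    _write_table(
        pd.DataFrame([dataclasses.asdict(r) for r in result.posthoc]),
        out_dir / "posthoc.csv",
        cfg,
    )
    _write_table(result.overstay.condition_summary, out_dir / "overstay_summary.csv", cfg)
    _write_table(result.overstay.by_patch_visit, out_dir / "overstay_by_visit.csv", cfg)
    _write_table(result.bins, out_dir / "bin_summary.csv", cfg)
    _write_table(result.correlations, out_dir / "correlations.csv", cfg)
    with open(out_dir / "run_summary.txt", "w", encoding="utf-8") as fh:
        fh.write(_file_header(cfg))
        for key, value in result.summary.items():
            fh.write(f"{key}={value:.9g}\n" if isinstance(value, float) else f"{key}={value}\n")
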