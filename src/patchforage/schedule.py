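"""Stochastic depleting reward schedules for single patch visits.

A foraging patch delivers food pellets at random times while it is
occupied.  The nominal delivery rate starts at ``initial_rate`` (pellets
per second) on patch entry and decays exponentially with time constant
``decay_tau``.  Realized inter-pellet intervals are drawn from a normal
distribution whose mean is the reciprocal of the nominal rate and whose
spread is ``interval_sd``; draws are rejected and redrawn until strictly
positive.  The schedule resets to its maximal rate on every new patch
entry, so each visit is generated by a fresh call.

Two schedule variants are supported:

* **standard** — every delivery pays one pellet;
* **risky** — built from a standard realization by independently
  omitting each delivery with probability ``omission_prob`` (payout set
  to zero) and doubling the payout of survivors, which matches the mean
  of the standard schedule while doubling its variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.special import lambertw

__all__ = [
    "ScheduleParams",
    "DeliveryEvent",
    "PatchVisitSchedule",
    "ScheduleMoments",
    "generate_standard_schedule",
    "apply_risk_transform",
    "harvest_count",
    "expected_fluid_gain",
    "schedule_moments",
]

#: Session length (seconds) used as the default generation horizon.
DEFAULT_HORIZON = 1800.0


def _rng(seed) -> np.random.Generator:
    """Accept an int, a SeedSequence, a Generator, or None."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ScheduleParams:
    """Generative constants of a patch reward schedule.

    Parameters
    ----------
    initial_rate : float
        Nominal delivery rate at patch entry, pellets per second
        (default one pellet every 15 s).
    decay_tau : float
        Exponential decay time constant of the nominal rate, seconds.
    interval_sd : float
        Standard deviation of inter-pellet intervals, seconds.
    omission_prob : float
        Per-delivery omission probability (0 for the standard schedule,
        0.5 for the risky variant).
    pellets_per_delivery : int
        Pellets paid by each surviving delivery (1 standard, 2 risky).
    rate_at : {"draw", "delivery"}
        Where the "current" nominal rate is evaluated when drawing the
        next interval: at the moment of the previous delivery
        (``"draw"``, the default) or self-consistently at the projected
        delivery time (``"delivery"``).  The two readings differ only at
        second order but are both exposed because the optimum of the
        residence-time sweep is sensitive to fine generative detail.
    """

    initial_rate: float = 1.0 / 15.0
    decay_tau: float = 300.0
    interval_sd: float = 4.0
    omission_prob: float = 0.0
    pellets_per_delivery: int = 1
    rate_at: str = "draw"

    def __post_init__(self) -> None:
        if not self.initial_rate > 0:
            raise ValueError("initial_rate must be positive")
        if not self.decay_tau > 0:
            raise ValueError("decay_tau must be positive")
        if self.interval_sd < 0:
            raise ValueError("interval_sd must be non-negative")
        if not 0 <= self.omission_prob < 1:
            raise ValueError("omission_prob must lie in [0, 1)")
        if int(self.pellets_per_delivery) != self.pellets_per_delivery or self.pellets_per_delivery < 1:
            raise ValueError("pellets_per_delivery must be a positive integer")
        if self.rate_at not in ("draw", "delivery"):
            raise ValueError("rate_at must be 'draw' or 'delivery'")

    @classmethod
    def standard(cls, **overrides) -> "ScheduleParams":
        return cls(**overrides)

    @classmethod
    def risky(cls, **overrides) -> "ScheduleParams":
        overrides.setdefault("omission_prob", 0.5)
        overrides.setdefault("pellets_per_delivery", 2)
        return cls(**overrides)


class DeliveryEvent(NamedTuple):
    """A single timed pellet delivery (time in seconds since patch entry)."""

    time: float
    pellets: int


@dataclass(frozen=True)
class PatchVisitSchedule:
    """One realized sequence of timed pellet deliveries for a patch visit."""

    params: ScheduleParams
    events: tuple[DeliveryEvent, ...]

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(t < 0 for t in times):
            raise ValueError("delivery times must be non-negative")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("delivery times must be strictly increasing")
        if any(e.pellets < 0 for e in self.events):
            raise ValueError("pellet counts must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return np.array([e.time for e in self.events], dtype=float)

    @property
    def pellets(self) -> np.ndarray:
        return np.array([e.pellets for e in self.events], dtype=int)

    def to_text(self, path) -> None:
        """Write the schedule as a two-column delimited table.

        The header comment carries the generating parameters so a file is
        self-describing.
        """
        p = self.params
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(
                "# patch visit schedule: initial_rate=%r decay_tau=%r interval_sd=%r "
                "omission_prob=%r pellets_per_delivery=%r rate_at=%s\n"
                % (p.initial_rate, p.decay_tau, p.interval_sd, p.omission_prob,
                   p.pellets_per_delivery, p.rate_at)
            )
            fh.write("time_s,pellets\n")
            for e in self.events:
                fh.write("%.9f,%d\n" % (e.time, e.pellets))

    @classmethod
    def from_text(cls, path) -> "PatchVisitSchedule":
        params = ScheduleParams()
        events = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    kv = dict(
                        tok.split("=", 1)
                        for tok in line.lstrip("# ").split(": ", 1)[-1].split()
                        if "=" in tok
                    )
                    params = ScheduleParams(
                        initial_rate=float(kv["initial_rate"]),
                        decay_tau=float(kv["decay_tau"]),
                        interval_sd=float(kv["interval_sd"]),
                        omission_prob=float(kv["omission_prob"]),
                        pellets_per_delivery=int(kv["pellets_per_delivery"]),
                        rate_at=kv.get("rate_at", "draw"),
                    )
                elif line and not line.startswith("time_s"):
                    t, n = line.split(",")
                    events.append(DeliveryEvent(float(t), int(n)))
        return cls(params=params, events=tuple(events))


# ---------------------------------------------------------------------------
# generation


def _mean_interval(params: ScheduleParams, t_now: np.ndarray) -> np.ndarray:
    """Mean of the next inter-pellet interval given the current patch time.

    Under ``rate_at="draw"`` the mean is 1/rate evaluated at ``t_now``.
    Under ``rate_at="delivery"`` the mean ``mu`` solves the fixed point
    mu = 1/rate(t_now + mu), i.e. mu = -tau * W(-a/tau) with
    a = exp(t_now/tau)/r0 (principal Lambert-W branch).
    """
    a = np.exp(t_now / params.decay_tau) / params.initial_rate
    if params.rate_at == "draw":
        return a
    arg = -a / params.decay_tau
    if np.any(arg < -1.0 / np.e):
        raise FloatingPointError("no self-consistent interval: rate decays too fast")
    return -params.decay_tau * np.real(lambertw(arg))


def _delivery_times_batch(
    params: ScheduleParams,
    horizon: float,
    n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Delivery times for ``n`` independent schedule realizations.

    Returns flat arrays ``(rep, time)`` with one entry per delivery,
    ordered by delivery index (times within a replicate are increasing).
    """
    t = np.zeros(n)
    alive = np.arange(n)
    rep_chunks: list[np.ndarray] = []
    time_chunks: list[np.ndarray] = []
    while alive.size:
        mu = _mean_interval(params, t[alive])
        if params.interval_sd == 0:
            draw = mu
        else:
            draw = rng.normal(mu, params.interval_sd)
            bad = draw <= 0  # intervals must be strictly positive
            while bad.any():
                draw[bad] = rng.normal(mu[bad], params.interval_sd)
                bad = draw <= 0
        t_new = t[alive] + draw
        t[alive] = t_new
        keep = t_new <= horizon
        rep_chunks.append(alive[keep])
        time_chunks.append(t_new[keep])
        alive = alive[keep]
    if not rep_chunks:
        return np.empty(0, dtype=int), np.empty(0)
    return np.concatenate(rep_chunks), np.concatenate(time_chunks)


def generate_standard_schedule(
    params: ScheduleParams = ScheduleParams(),
    horizon: float = DEFAULT_HORIZON,
    seed=None,
) -> PatchVisitSchedule:
    """Realize one standard-schedule patch visit.

    Starting from patch entry at ``t = 0``, each inter-pellet interval is
    drawn from a normal distribution with mean equal to the reciprocal of
    the nominal rate (see :class:`ScheduleParams.rate_at`) and spread
    ``interval_sd``, redrawing non-positive values, until the next
    delivery would fall beyond ``horizon``.  Every delivery pays
    ``pellets_per_delivery`` pellets.
    """
    if not horizon > 0:
        raise ValueError("horizon must be positive")
    if params.omission_prob != 0:
        raise ValueError(
            "generate_standard_schedule requires omission_prob == 0; "
            "use apply_risk_transform for the risky variant"
        )
    rep, times = _delivery_times_batch(params, horizon, 1, _rng(seed))
    events = tuple(
        DeliveryEvent(float(t), int(params.pellets_per_delivery)) for t in np.sort(times)
    )
    return PatchVisitSchedule(params=params, events=events)


def apply_risk_transform(
    schedule: PatchVisitSchedule,
    omission_prob: float = 0.5,
    magnitude_multiplier: int = 2,
    seed=None,
    drop_omitted: bool = False,
) -> PatchVisitSchedule:
    """Derive a risky schedule from a realized standard schedule.

    Delivery times are kept.  Each delivery is independently omitted
    with probability ``omission_prob``; omitted deliveries are retained
    as zero-pellet events (or dropped entirely if ``drop_omitted``),
    and survivors pay ``pellets * magnitude_multiplier``.  With the
    default omission probability 0.5 and multiplier 2, expected payout
    matches the input schedule while variance doubles.
    """
    if not 0 <= omission_prob < 1:
        raise ValueError("omission_prob must lie in [0, 1)")
    if magnitude_multiplier < 1:
        raise ValueError("magnitude_multiplier must be a positive integer")
    rng = _rng(seed)
    omitted = rng.random(len(schedule.events)) < omission_prob
    events = []
    for e, om in zip(schedule.events, omitted):
        if om:
            if not drop_omitted:
                events.append(DeliveryEvent(e.time, 0))
        else:
            events.append(DeliveryEvent(e.time, e.pellets * magnitude_multiplier))
    new_params = replace(
        schedule.params,
        omission_prob=omission_prob,
        pellets_per_delivery=schedule.params.pellets_per_delivery * magnitude_multiplier,
    )
    return PatchVisitSchedule(params=new_params, events=tuple(events))


def harvest_count(schedule: PatchVisitSchedule, residence: float) -> int:
    """Pellets collected by an agent that stays ``residence`` seconds.

    All pellets delivered at times ``<= residence`` are harvested; the
    count is monotone non-decreasing in ``residence``.
    """
    if residence < 0:
        raise ValueError("residence must be non-negative")
    if not schedule.events:
        return 0
    times = schedule.times
    return int(schedule.pellets[times <= residence].sum())


def expected_fluid_gain(params: ScheduleParams, residence) -> float | np.ndarray:
    """Continuous-deposition (fluid-limit) cumulative gain.

    If pellet mass were deposited continuously at the nominal rate
    ``r0 * exp(-t/tau)``, the amount collected by time ``T`` would be
    ``r0 * tau * (1 - exp(-T/tau))``.  This closed form is the analytic
    reference used by the marginal-value-theorem oracle; it is not the
    generative model (real deliveries are discrete pellets).
    """
    residence = np.asarray(residence, dtype=float)
    if np.any(residence < 0):
        raise ValueError("residence must be non-negative")
    out = params.initial_rate * params.decay_tau * (
        1.0 - np.exp(-residence / params.decay_tau)
    )
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ScheduleMoments:
    """Monte-Carlo harvest moments for the standard schedule and its risky twin."""

    residence: float
    n_reps: int
    mean_standard: float
    var_standard: float
    mean_risky: float
    var_risky: float

    @property
    def se_mean_standard(self) -> float:
        return float(np.sqrt(self.var_standard / self.n_reps))

    @property
    def se_mean_risky(self) -> float:
        return float(np.sqrt(self.var_risky / self.n_reps))


def _harvest_counts_batch(
    params: ScheduleParams,
    residence: float,
    n_reps: int,
    rng: np.random.Generator,
    risky: bool,
    omission_prob: float = 0.5,
    magnitude_multiplier: int = 2,
) -> np.ndarray:
    """Per-replicate harvested pellets at a fixed residence (vectorized)."""
    rep, times = _delivery_times_batch(params, residence, n_reps, rng)
    if risky:
        weights = np.where(
            rng.random(times.size) < omission_prob,
            0.0,
            float(params.pellets_per_delivery * magnitude_multiplier),
        )
    else:
        weights = np.full(times.size, float(params.pellets_per_delivery))
    return np.bincount(rep, weights=weights, minlength=n_reps)


def schedule_moments(
    params: ScheduleParams = ScheduleParams(),
    residence: float = 120.0,
    n_reps: int = 10_000,
    seed=None,
) -> ScheduleMoments:
    """Monte-Carlo mean and variance of the harvest at a fixed residence.

    The standard schedule and its risk transform (omission 0.5, doubled
    payout) are simulated on the same parameter base with independent
    realizations.  By construction the two means agree in expectation
    while Var(risky) = Var(standard) + E[standard count] (law of total
    variance with per-event payout 2*Bernoulli(0.5)).
    """
    if residence < 0:
        raise ValueError("residence must be non-negative")
    if n_reps < 2:
        raise ValueError("n_reps must be at least 2")
    rng = _rng(seed)
    if residence == 0:
        return ScheduleMoments(residence, n_reps, 0.0, 0.0, 0.0, 0.0)
    std = _harvest_counts_batch(params, residence, n_reps, rng, risky=False)
    rsk = _harvest_counts_batch(params, residence, n_reps, rng, risky=True)
    return ScheduleMoments(
        residence=residence,
        n_reps=n_reps,
        mean_standard=float(std.mean()),
        var_standard=float(std.var(ddof=1)),
        mean_risky=float(rsk.mean()),
        var_risky=float(rsk.var(ddof=1)),
    )
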