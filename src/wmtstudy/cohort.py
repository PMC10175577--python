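"""Synthetic cohort generation for a spaced-vs-massed training study.

Generates a full four-arm study: alternating allocation to a distributed
(2 sessions/week for 8 weeks) or intensive (4 sessions/week for 4 weeks)
schedule, 1:1 blocked randomisation to working-memory training (WMT) or
active control within schedule, task-order counterbalancing, session
calendars obeying the schedule spacing rules, 16 per-session training
outcomes per task, pre/post transfer scores, acceptability ratings, and
missing-completely-at-random attrition.

Trained participants follow a piecewise-linear-with-plateau latent
capacity curve

    c_t = baseline + slope1 * min(t, knot) + slope2 * max(0, t - knot)

(sessions t = 1..16), so the downstream one-knot spline analysis is
correctly specified and parameter recovery is meaningful.  Active
controls have slope1 = slope2 = 0.  Session outcomes are produced either
by the full per-screen task engine with a logistic responder (default,
``training_model="engine"``) or by a cheap outcome-level emulation
(Gaussian noise around c_t, quantised to the staircase-outcome grid of
fifths) for large Monte Carlo runs (``training_model="outcome"``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from . import task_engine as te
from . import transfer as tr

__all__ = [
    "LearnerParams",
    "CohortConfig",
    "ParticipantRecord",
    "Cohort",
    "ScheduleReport",
    "allocate_groups",
    "build_calendar",
    "validate_schedule",
    "sample_learner_params",
    "simulate_participant",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]

SCHEDULES = ("distributed", "intensive")
TREATMENTS = ("WMT", "active-control")
TASKS = ("verbal", "spatial")
N_SESSIONS = 16

# within-study day offsets implied by the spacing rules
DISTRIBUTED_OFFSETS = tuple(7 * w + d for w in range(8) for d in (0, 2))
INTENSIVE_OFFSETS = tuple(7 * w + d for w in range(4) for d in (0, 1, 2, 3))
_OFFSETS = {"distributed": DISTRIBUTED_OFFSETS, "intensive": INTENSIVE_OFFSETS}


@dataclass(frozen=True)
class LearnerParams:
    """Latent parameters of one learner's training trajectory.

    ``slope1``/``slope2`` are capacity per session before/after the
    plateau onset ``knot_session``; ``discrim`` and ``lapse`` parametrise
    the logistic per-screen responder.
    """

    baseline: float
    slope1: float
    slope2: float
    knot_session: int
    discrim: float = 3.0
    lapse: float = 0.05

    def __post_init__(self) -> None:
        if self.baseline < 1:
            raise ValueError("baseline capacity must be >= 1")
        if self.slope1 < self.slope2:
            raise ValueError("slope1 must be >= slope2")
        if not 0 <= self.lapse <= 0.2:
            raise ValueError("lapse must lie in [0, 0.2]")

    @property
    def gain(self) -> float:
        """Capacity increment from session 1 to the plateau onset."""
        return self.slope1 * (self.knot_session - 1)

    def capacity(self, t: int | np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (self.baseline + self.slope1 * np.minimum(t, self.knot_session)
                + self.slope2 * np.maximum(0.0, t - self.knot_session))


@dataclass(frozen=True)
class CohortConfig:
    """Study-level generator settings.

    Defaults emulate the study conditions: 20 enrolled per arm with ~10%
    missing-completely-at-random attrition (about 18 completers per arm),
    no programmed transfer or practice effect, learner heterogeneity
    giving a large training effect (first-session capacity near 2,
    plateau onset around session 8, smoothed-scale learning rates around
    0.1 level per session).
    """

    n_per_group: int = 20
    attrition_prob: float = 0.10
    treatment_transfer_effect: float = 0.0  # SD units, WMT post only
    session_effect: float = 0.0  # SD units, everyone's post scores
    seed: int = 0
    start_date: str = "2021-06-01"  # a Tuesday
    training_model: str = "engine"  # "engine" | "outcome"
    # learner population
    baseline_mean: float = 2.0
    baseline_sd: float = 0.5
    slope1_mean: float = 0.12
    slope1_sd: float = 0.06
    slope2_mean: float = 0.01
    knot_low: int = 5
    knot_high: int = 11
    discrim: float = 3.0
    # session-to-session outcome volatility of the outcome-level model,
    # calibrated to the engine's stationary session-outcome SD (~0.15)
    outcome_sd: float = 0.15
    # transfer populations (latent mean, SD)
    dsf_mean: float = 6.5
    dsf_sd: float = 1.2
    dsb_mean: float = 5.0
    dsb_sd: float = 1.2
    retest_noise: float = 0.5  # SD units of pre->post latent noise
    questionnaire_prob: float = 66 / 71

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if not 0 <= self.attrition_prob <= 1:
            raise ValueError("attrition_prob must lie in [0, 1]")
        if self.training_model not in ("engine", "outcome"):
            raise ValueError("training_model must be 'engine' or 'outcome'")


@dataclass
class ParticipantRecord:
    id: str
    schedule: str
    treatment: str
    task_order_first_session: str  # "verbal-first" | "spatial-first"
    age: float = np.nan
    sex: str = ""
    completed: bool = True
    dropout_session: int | None = None  # first missed session, if any
    session_dates: list[date] = field(default_factory=list)
    verbal_outcomes: list[float] = field(default_factory=list)
    spatial_outcomes: list[float] = field(default_factory=list)
    dsf_pre: float = np.nan
    dsf_post: float = np.nan
    dsb_pre: float = np.nan
    dsb_post: float = np.nan
    rr_pre: float = np.nan
    rr_post: float = np.nan
    questionnaire_completed: bool = False
    likert_challenging: float = np.nan
    likert_engaging: float = np.nan
    likert_adopt: float = np.nan
    likert_schedule: float = np.nan

    @property
    def group(self) -> str:
        return f"{self.schedule}-{self.treatment}"


@dataclass
class Cohort:
    participants: list[ParticipantRecord]
    config: CohortConfig

    def __len__(self) -> int:
        return len(self.participants)

    def participants_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.participants:
            rows.append({
                "participant": p.id, "schedule": p.schedule,
                "treatment": p.treatment, "group": p.group,
                "task_order_first_session": p.task_order_first_session,
                "age": p.age, "sex": p.sex, "completed": p.completed,
                "dropout_session": (np.nan if p.dropout_session is None
                                    else p.dropout_session),
                "dsf_pre": p.dsf_pre, "dsf_post": p.dsf_post,
                "dsb_pre": p.dsb_pre, "dsb_post": p.dsb_post,
                "rr_pre": p.rr_pre, "rr_post": p.rr_post,
                "questionnaire_completed": p.questionnaire_completed,
                "likert_challenging": p.likert_challenging,
                "likert_engaging": p.likert_engaging,
                "likert_adopt": p.likert_adopt,
                "likert_schedule": p.likert_schedule,
            })
        return pd.DataFrame(rows)

    def sessions_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.participants:
            outcomes = {"verbal": p.verbal_outcomes,
                        "spatial": p.spatial_outcomes}
            for task in TASKS:
                for t in range(1, N_SESSIONS + 1):
                    done = t <= len(p.session_dates)
                    rows.append({
                        "participant": p.id, "schedule": p.schedule,
                        "treatment": p.treatment, "group": p.group,
                        "task": task, "session": t,
                        "date": (p.session_dates[t - 1].isoformat()
                                 if done else ""),
                        "mean_nback": (outcomes[task][t - 1]
                                       if done else np.nan),
                    })
        return pd.DataFrame(rows)


def allocate_groups(n_total: int, rng: np.random.Generator,
                    ) -> list[tuple[str, str, str]]:
    """Allocate ``n_total`` enrolees to (schedule, treatment, task order).

    Schedules alternate by enrolment order.  Within each schedule,
    treatment is assigned 1:1 by blocked randomisation (random order
    within consecutive pairs).  Task order on session 1 is
    counterbalanced within each of the four arms.
    """
    if n_total < 4:
        raise ValueError("need at least four enrolees")
    schedules = [SCHEDULES[i % 2] for i in range(n_total)]
    treatments: list[str] = [""] * n_total
    for sched in SCHEDULES:
        idx = [i for i, s in enumerate(schedules) if s == sched]
        for j in range(0, len(idx), 2):
            pair = list(TREATMENTS)
            rng.shuffle(pair)
            for k, i in enumerate(idx[j:j + 2]):
                treatments[i] = pair[k]
    order_count: dict[str, int] = {}
    orders: list[str] = []
    for sched, treat in zip(schedules, treatments):
        key = f"{sched}-{treat}"
        c = order_count.get(key, 0)
        orders.append("verbal-first" if c % 2 == 0 else "spatial-first")
        order_count[key] = c + 1
    return list(zip(schedules, treatments, orders))


def build_calendar(schedule: str, start_date: date,
                   rng: np.random.Generator | None = None) -> list[date]:
    """The 16 session dates implied by the schedule's spacing rules.

    Distributed: two sessions per week with a 2-day gap, weeks 7 days
    apart (e.g., Tue/Thu for 8 weeks).  Intensive: four consecutive days
    per week for 4 weeks (e.g., Tue-Fri).
    """
    if schedule not in _OFFSETS:
        raise ValueError(f"unknown schedule {schedule!r}")
    return [start_date + timedelta(days=o) for o in _OFFSETS[schedule]]


@dataclass(frozen=True)
class ScheduleReport:
    valid: bool
    complete: bool
    violations: tuple[str, ...]


def validate_schedule(dates: list[date], schedule: str) -> ScheduleReport:
    """Check 16 dates against the schedule pattern anchored at the first.

    An incomplete calendar (fewer than 16 dates) is reported as invalid
    and incomplete rather than raising: it signals a non-completer.
    """
    if schedule not in _OFFSETS:
        raise ValueError(f"unknown schedule {schedule!r}")
    if len(dates) < N_SESSIONS:
        return ScheduleReport(
            valid=False, complete=False,
            violations=(f"incomplete: {len(dates)} of {N_SESSIONS} sessions",))
    if len(dates) > N_SESSIONS:
        return ScheduleReport(valid=False, complete=True, violations=(
            f"too many sessions: {len(dates)}",))
    expected = _OFFSETS[schedule]
    offsets = [(d - dates[0]).days for d in dates]
    sessions_per_week = 2 if schedule == "distributed" else 4
    violations = []
    for i, (got, want) in enumerate(zip(offsets, expected)):
        if got != want:
            week = i // sessions_per_week + 1
            violations.append(
                f"session {i + 1} (week {week}): day offset {got}, "
                f"expected {want}")
    return ScheduleReport(valid=not violations, complete=True,
                          violations=tuple(violations))


def sample_learner_params(treatment: str, config: CohortConfig,
                          rng: np.random.Generator) -> LearnerParams:
    """Draw one learner's latent trajectory from the population model."""
    baseline = max(1.0, rng.normal(config.baseline_mean, config.baseline_sd))
    lapse = float(rng.uniform(0.02, 0.10))
    if treatment == "WMT":
        slope1 = max(0.01, rng.normal(config.slope1_mean, config.slope1_sd))
        slope2 = float(np.clip(rng.normal(config.slope2_mean, 0.01),
                               0.0, slope1))
        knot = int(rng.integers(config.knot_low, config.knot_high + 1))
    else:
        slope1 = slope2 = 0.0
        knot = 8  # irrelevant with zero slopes
    return LearnerParams(baseline=baseline, slope1=slope1, slope2=slope2,
                         knot_session=knot, discrim=config.discrim,
                         lapse=lapse)


def _training_series(params: LearnerParams, config: CohortConfig,
                     n_sessions: int, rng: np.random.Generator,
                     ) -> dict[str, list[float]]:
    series: dict[str, list[float]] = {t: [] for t in TASKS}
    caps = params.capacity(np.arange(1, n_sessions + 1))
    if config.training_model == "engine":
        task_cfgs = {"verbal": te.TaskConfig.verbal(),
                     "spatial": te.TaskConfig.spatial()}
        for t in range(n_sessions):
            responder = te.LogisticResponder(
                capacity=float(caps[t]), discrim=params.discrim,
                lapse=params.lapse)
            for task in TASKS:
                rec = te.run_session(responder, task_cfgs[task], rng)
                series[task].append(rec.outcome)
    else:
        for task in TASKS:
            noisy = caps + rng.normal(0.0, config.outcome_sd, size=n_sessions)
            # staircase outcomes are means of 5 integer levels >= 1
            vals = np.maximum(1.0, np.round(noisy * 5.0) / 5.0)
            series[task] = [float(v) for v in vals]
    return series


def _transfer_scores(record: ParticipantRecord, config: CohortConfig,
                     rng: np.random.Generator) -> None:
    is_wmt = record.treatment == "WMT"
    shift = config.session_effect + (config.treatment_transfer_effect
                                     if is_wmt else 0.0)
    # forward span
    pre = rng.normal(config.dsf_mean, config.dsf_sd)
    post = pre + shift * config.dsf_sd + rng.normal(
        0.0, config.retest_noise * config.dsf_sd)
    record.dsf_pre = tr.simulate_digit_span(pre, tr.DSF_PROTOCOL, rng,
                                            noise_sd=0.4).span
    record.dsf_post = tr.simulate_digit_span(post, tr.DSF_PROTOCOL, rng,
                                             noise_sd=0.4).span
    # backward span
    pre = rng.normal(config.dsb_mean, config.dsb_sd)
    post = pre + shift * config.dsb_sd + rng.normal(
        0.0, config.retest_noise * config.dsb_sd)
    record.dsb_pre = tr.simulate_digit_span(pre, tr.DSB_PROTOCOL, rng,
                                            noise_sd=0.4).span
    record.dsb_post = tr.simulate_digit_span(post, tr.DSB_PROTOCOL, rng,
                                             noise_sd=0.4).span
    # relational reasoning, latent ability on a z-score scale
    pre = rng.normal(0.0, 1.0)
    post = pre + shift + rng.normal(0.0, config.retest_noise)
    record.rr_pre = tr.simulate_reasoning(pre, rng)
    record.rr_post = tr.simulate_reasoning(post, rng)
    if not record.completed:
        record.dsf_post = np.nan
        record.dsb_post = np.nan
        record.rr_post = np.nan
        if record.dropout_session == 1:  # never reached the baseline tasks
            record.dsf_pre = np.nan
            record.dsb_pre = np.nan
            record.rr_pre = np.nan


_LIKERT_PROBS = {
    # majority agreement profiles for the four acceptability statements
    "likert_challenging": (0.01, 0.02, 0.05, 0.46, 0.46),
    "likert_engaging": (0.02, 0.05, 0.17, 0.46, 0.30),
    "likert_adopt": (0.03, 0.10, 0.22, 0.40, 0.25),
    "likert_schedule": (0.03, 0.07, 0.30, 0.40, 0.20),
}


def simulate_participant(params: LearnerParams, record: ParticipantRecord,
                         config: CohortConfig,
                         rng: np.random.Generator) -> ParticipantRecord:
    """Fill a participant skeleton with dates, outcomes and scores."""
    record.age = float(np.clip(rng.normal(65.89, 6.78), 55.0, 85.0))
    record.sex = "male" if rng.random() < 21 / 79 else "female"
    calendar = build_calendar(record.schedule,
                              date.fromisoformat(config.start_date), rng)
    if rng.random() < config.attrition_prob:
        record.completed = False
        record.dropout_session = int(rng.integers(1, N_SESSIONS + 1))
    n_done = N_SESSIONS if record.completed else record.dropout_session - 1
    record.session_dates = calendar[:n_done]
    series = _training_series(params, config, n_done, rng)
    record.verbal_outcomes = series["verbal"]
    record.spatial_outcomes = series["spatial"]
    _transfer_scores(record, config, rng)
    if record.completed and rng.random() < config.questionnaire_prob:
        record.questionnaire_completed = True
        for col, probs in _LIKERT_PROBS.items():
            setattr(record, col, float(rng.choice([1, 2, 3, 4, 5], p=probs)))
    return record


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Simulate the full study defined by ``config``.

    All randomness descends from ``config.seed``; each participant gets
    an independent child stream, so cohorts are reproducible and
    participants are exchangeable.
    """
    root = np.random.SeedSequence(config.seed)
    alloc_seed, *p_seeds = root.spawn(4 * config.n_per_group + 1)
    alloc = allocate_groups(4 * config.n_per_group,
                            np.random.default_rng(alloc_seed))
    participants = []
    for i, ((sched, treat, order), seq) in enumerate(zip(alloc, p_seeds)):
        rng = np.random.default_rng(seq)
        record = ParticipantRecord(id=f"P{i + 1:03d}", schedule=sched,
                                   treatment=treat,
                                   task_order_first_session=order)
        params = sample_learner_params(treat, config, rng)
        participants.append(
            simulate_participant(params, record, config, rng))
    return Cohort(participants=participants, config=config)


def write_cohort(cohort: Cohort, path: str | Path) -> dict[str, Path]:
    """Write ``participants.csv`` and ``sessions.csv`` under ``path``.

    Output is deterministic byte-for-byte for a given cohort.
    """
    if not cohort.participants:
        raise ValueError("empty cohort")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, frame in (("participants", cohort.participants_frame()),
                        ("sessions", cohort.sessions_frame())):
        f = path / f"{name}.csv"
        frame.to_csv(f, index=False, float_format="%.10g",
                     lineterminator="\n")
        files[name] = f
    return files


def read_cohort(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the (participants, sessions) frames written by write_cohort."""
    path = Path(path)
    participants = pd.read_csv(path / "participants.csv")
    sessions = pd.read_csv(path / "sessions.csv")
    return participants, sessions
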