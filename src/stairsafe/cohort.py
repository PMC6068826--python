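"""Reproducible synthetic cohorts, staircases and descent trials.

Emulates the statistical structure of the field study's data so the whole
pipeline is testable without raw video: grade-stratified truncated-normal
anthropometrics, scenario-dependent descent speeds, posterior foot
clearance centred near 0.1 m, anterior foot clearance centred slightly
below zero, and occasional within-descent pauses (evacuation scenario
only).  All randomness flows from one seed; identical seed and config
give identical output, byte for byte once written to CSV.
"""

from __future__ import annotations

import zlib
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator
from scipy import stats

from . import reference
from .gait import SCENARIOS, DescentTrial
from .stability import StaircaseSpec

__all__ = [
    "Normal",
    "GradeParams",
    "CohortConfig",
    "generate_cohort",
    "generate_trials",
    "trials_to_frame",
    "frame_to_trials",
    "write_cohort_csv",
    "read_cohort_csv",
]

COHORT_COLUMNS = [
    "subject_id", "grade", "age_yr", "height_cm",
    "shoulder_width_m", "l_m", "foot_length_m", "eta_m",
]

TRIAL_COLUMNS = [
    "subject_id", "trial", "scenario", "site",
    "step_index", "crossing_time_s", "pause_s", "pfc_m", "afc_m",
]


class Normal(BaseModel):
    """Mean/SD pair for one generated quantity."""

    model_config = dict(frozen=True)
    mean: float
    sd: float = Field(ge=0)


def _norm(pair) -> Normal:
    if isinstance(pair, Normal):
        return pair
    if isinstance(pair, Mapping):
        return Normal(**pair)
    m, s = pair
    return Normal(mean=m, sd=s)


class GradeParams(BaseModel):
    """Per-grade anthropometric distributions."""

    model_config = dict(frozen=True)
    age_yr: Normal
    height_cm: Normal
    shoulder_width_m: Normal
    l_m: Normal
    foot_length_m: Normal


def _default_grades() -> dict[int, GradeParams]:
    return {
        g: GradeParams(**{k: _norm(v) for k, v in row.items()})
        for g, row in reference.GRADE_ANTHROPOMETRICS.items()
    }


class CohortConfig(BaseModel):
    """Full specification of a synthetic cohort and its descent trials.

    Defaults reproduce the study conditions: 12 students per grade in
    grades 1-6, grade anthropometrics from the published table,
    scenario speeds alone 0.91 +/- 0.13, paired 0.82 +/- 0.10 and
    evacuation 0.88 +/- 0.08 m/s, posterior foot clearance
    0.084 +/- 0.02 m, anterior foot clearance -0.02 +/- 0.02 m, and
    pauses (evacuation only) on ~30% of steps lasting 1.5 +/- 0.4 s.
    Lengths and speeds are drawn from normals truncated at zero; AFC is
    plain normal because negative values (toe overhang) are meaningful.
    """

    model_config = dict(frozen=True)

    n_per_grade: int = Field(default=12, gt=0)
    grades: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    anthropometrics: dict[int, GradeParams] = Field(default_factory=_default_grades)
    eta_m: Normal = _norm(reference.ETA_M)
    scenario_speeds: dict[str, Normal] = Field(
        default_factory=lambda: {k: _norm(v) for k, v in reference.SCENARIO_SPEEDS.items()}
    )
    pfc_m: Normal = _norm(reference.PFC_M)
    afc_m: Normal = _norm(reference.AFC_M)
    pause_prob: float = Field(default=0.3, ge=0, le=1)
    pause_duration_s: Normal = Normal(mean=1.5, sd=0.4)
    trials_per_subject: int = Field(default=2, ge=1)
    seed: int = 0

    @field_validator("grades")
    @classmethod
    def _grades_nonempty(cls, v):
        if not v:
            raise ValueError("grades must be non-empty")
        if any(g < 1 or g > 6 for g in v):
            raise ValueError("grades must be within 1..6")
        return v


def _truncated_normal(rng: np.random.Generator, dist: Normal, size: int,
                      lower: float = 0.0) -> np.ndarray:
    """Draw from Normal(mean, sd) truncated below at ``lower``."""
    if dist.sd == 0:
        return np.full(size, dist.mean)
    a = (lower - dist.mean) / dist.sd
    return stats.truncnorm.rvs(a, np.inf, loc=dist.mean, scale=dist.sd,
                               size=size, random_state=rng)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw one synthetic cohort of student anthropometrics.

    Returns a DataFrame with one row per student and columns
    ``subject_id, grade, age_yr, height_cm, shoulder_width_m, l_m,
    foot_length_m, eta_m``.  Lengths are truncated-normal above zero and
    the heel-to-CoP distance eta is redrawn until it is strictly inside
    the foot (eta < L).
    """
    rng = np.random.default_rng(config.seed)
    frames = []
    sid = 1
    for grade in config.grades:
        try:
            p = config.anthropometrics[grade]
        except KeyError:
            raise KeyError(f"no anthropometric parameters for grade {grade}")
        n = config.n_per_grade
        L = _truncated_normal(rng, p.foot_length_m, n)
        eta = _truncated_normal(rng, config.eta_m, n)
        for _ in range(1000):
            bad = eta >= L
            if not bad.any():
                break
            eta[bad] = _truncated_normal(rng, config.eta_m, int(bad.sum()))
        else:
            raise RuntimeError("could not draw eta < foot length; check parameters")
        frames.append(pd.DataFrame({
            "subject_id": np.arange(sid, sid + n),
            "grade": grade,
            "age_yr": _truncated_normal(rng, p.age_yr, n),
            "height_cm": _truncated_normal(rng, p.height_cm, n),
            "shoulder_width_m": _truncated_normal(rng, p.shoulder_width_m, n),
            "l_m": _truncated_normal(rng, p.l_m, n),
            "foot_length_m": L,
            "eta_m": eta,
        }))
        sid += n
    return pd.concat(frames, ignore_index=True)[COHORT_COLUMNS]


def _trial_rng(config: CohortConfig, staircase: StaircaseSpec, scenario: str):
    # independent, reproducible stream per (seed, site, scenario)
    site_key = zlib.crc32(staircase.name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(
        [config.seed, site_key, SCENARIOS.index(scenario)]
    )


def generate_trials(
    cohort: pd.DataFrame,
    staircase: StaircaseSpec,
    scenario: str,
    config: CohortConfig,
) -> list[DescentTrial]:
    """Simulate timed descents of ``staircase`` for every cohort member.

    Each subject contributes ``config.trials_per_subject`` trials.  A
    horizontal speed v is drawn per trial from the scenario's
    distribution; crossing times accumulate one dwell ``d / v`` per step
    so that the speed formula recovers v exactly when no pauses are
    injected.  In the evacuation scenario each step independently
    carries a pause with probability ``pause_prob``; the injected pause
    total is recorded on the trial as ground truth.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if staircase.n_steps < 2:
        raise ValueError("staircase must have at least 2 steps")
    rng = _trial_rng(config, staircase, scenario)
    d, n_steps = staircase.step_depth, staircase.n_steps
    trials = []
    for _, subject in cohort.iterrows():
        for trial_no in range(1, config.trials_per_subject + 1):
            v = float(_truncated_normal(rng, config.scenario_speeds[scenario], 1)[0])
            dwell = d / v
            pauses = np.zeros(n_steps)
            if scenario == "evacuation" and config.pause_prob > 0:
                paused = rng.random(n_steps) < config.pause_prob
                if paused.any():
                    pauses[paused] = _truncated_normal(
                        rng, config.pause_duration_s, int(paused.sum())
                    )
            times = dwell * np.arange(1, n_steps + 1) + np.cumsum(pauses)
            events = ((0, 0.0),) + tuple(
                (k, float(times[k - 1])) for k in range(1, n_steps + 1)
            )
            trials.append(DescentTrial(
                subject_id=int(subject["subject_id"]),
                scenario=scenario,
                site=staircase.name,
                events=events,
                pfc=float(_truncated_normal(rng, config.pfc_m, 1)[0]),
                afc=float(rng.normal(config.afc_m.mean, config.afc_m.sd))
                if config.afc_m.sd > 0 else config.afc_m.mean,
                Tp=float(pauses.sum()),
                trial=trial_no,
                v_drawn=v,
            ))
    return trials


# ---------------------------------------------------------------------------
# Tabular round trips.  Trials serialise long: one row per step-crossing
# event, trial-level values (clearances, pauses) repeated on each row.

def trials_to_frame(trials: Sequence[DescentTrial]) -> pd.DataFrame:
    rows = []
    for t in trials:
        for (k, time) in t.events:
            rows.append(dict(
                subject_id=t.subject_id, trial=t.trial, scenario=t.scenario,
                site=t.site, step_index=k, crossing_time_s=time,
                pause_s=0.0, pfc_m=t.pfc, afc_m=t.afc,
            ))
    df = pd.DataFrame(rows)[TRIAL_COLUMNS]
    # store each trial's pause total on its step-0 row
    totals = {(t.subject_id, t.trial, t.scenario, t.site): t.Tp for t in trials}
    mask = df["step_index"] == 0
    df.loc[mask, "pause_s"] = [
        totals[key] for key in zip(
            df.loc[mask, "subject_id"], df.loc[mask, "trial"],
            df.loc[mask, "scenario"], df.loc[mask, "site"],
        )
    ]
    return df


def frame_to_trials(df: pd.DataFrame) -> list[DescentTrial]:
    trials = []
    for (sid, trial, scenario, site), grp in df.groupby(
        ["subject_id", "trial", "scenario", "site"], sort=True
    ):
        grp = grp.sort_values("step_index")
        events = tuple(
            (int(k), float(t))
            for k, t in zip(grp["step_index"], grp["crossing_time_s"])
        )
        trials.append(DescentTrial(
            subject_id=int(sid), scenario=scenario, site=site, events=events,
            pfc=float(grp["pfc_m"].iloc[0]), afc=float(grp["afc_m"].iloc[0]),
            Tp=float(grp["pause_s"].sum()), trial=int(trial),
        ))
    return trials


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort[COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)[COHORT_COLUMNS]
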