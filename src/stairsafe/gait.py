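"""Per-trial and aggregate gait statistics for stair descent.

The central quantity is the pause-corrected horizontal descent speed

    ``v = N * d / (T - Tp)``

where ``N`` is the number of steps traversed, ``d`` the step depth, ``T``
the total traversal time and ``Tp`` the summed pause time.  Descents
alone or in a pair are treated as continuous (``Tp = 0``); only in the
evacuation scenario are pauses removed, because there a walker's timing
is dictated by the surrounding crowd.

Trials carry their events as ``(step_index, crossing_time)`` pairs whose
first row is the departure from the top landing (step index 0, t = 0),
so a flight of ``N`` steps has exactly ``N`` dwell intervals and the
speed formula round-trips exactly on pause-free synthetic data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference

__all__ = [
    "SCENARIOS",
    "DescentTrial",
    "GaitSummary",
    "SampleStats",
    "ReferencePolicy",
    "detect_pauses",
    "descent_speed",
    "summarize",
    "select_reference_parameters",
]

SCENARIOS = ("alone", "paired", "evacuation")

#: Default dwell threshold for pause detection, seconds.  Under typical
#: speeds (~0.9 m/s) and depths (~0.28 m) a normal dwell is ~0.3 s; the
#: threshold sits roughly two dwell-SDs above the mean dwell.
DWELL_THRESHOLD_S = 0.8


@dataclass(frozen=True)
class DescentTrial:
    """One subject's timed traversal of a flight of stairs.

    ``events`` is an ordered tuple of ``(step_index, crossing_time_s)``;
    the first entry is the departure from the top landing.  ``pfc`` and
    ``afc`` are the trial-mean posterior/anterior foot clearances in
    metres (AFC negative when the toes overhang the edge).  ``Tp`` is
    the summed true pause time in seconds (recorded at generation time
    for synthetic trials; use :func:`detect_pauses` for event-only data).
    """

    subject_id: int
    scenario: str
    site: str
    events: tuple[tuple[int, float], ...]
    pfc: float
    afc: float
    Tp: float = 0.0
    trial: int = 1
    v_drawn: float | None = None  # synthetic ground truth, if known

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if len(self.events) < 2:
            raise ValueError("a trial needs at least two events")
        times = [t for _, t in self.events]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("crossing times must be strictly increasing")
        if self.Tp < 0:
            raise ValueError("pause time cannot be negative")
        if self.T <= self.Tp:
            raise ValueError(f"total time {self.T} must exceed pause time {self.Tp}")

    @property
    def T(self) -> float:
        """Total traversal time, s."""
        return self.events[-1][1] - self.events[0][1]

    @property
    def n_steps(self) -> int:
        """Number of steps traversed."""
        return self.events[-1][0] - self.events[0][0]


def detect_pauses(
    events: Sequence[tuple[int, float]],
    dwell_threshold: float = DWELL_THRESHOLD_S,
    scenario: str | None = None,
) -> float:
    """Total pause time from per-step dwells exceeding a threshold.

    ``Tp = sum(dwell_k - dwell_threshold)`` over steps whose dwell
    exceeds the threshold.  Descents alone or in a pair are continuous
    by definition, so passing their scenario forces ``Tp = 0``.

    Raises
    ------
    ValueError
        On fewer than two events or non-monotone crossing times.
    """
    if scenario is not None and scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if len(events) < 2:
        raise ValueError("need at least two events")
    times = np.asarray([t for _, t in events], dtype=float)
    dwells = np.diff(times)
    if np.any(dwells <= 0):
        raise ValueError("crossing times must be strictly increasing")
    if scenario in ("alone", "paired"):
        return 0.0
    excess = dwells - dwell_threshold
    return float(excess[excess > 0].sum())


def descent_speed(
    trial: DescentTrial, step_depth: float, Tp: float | None = None
) -> float:
    """Pause-corrected horizontal descent speed ``N * d / (T - Tp)`` in m/s.

    ``Tp`` defaults to the trial's recorded pause time in the evacuation
    scenario and to 0 otherwise (alone/paired descents are continuous).
    """
    if Tp is None:
        Tp = trial.Tp if trial.scenario == "evacuation" else 0.0
    denom = trial.T - Tp
    if denom <= 0:
        raise ValueError(
            f"corrupt trial: total time {trial.T} s does not exceed pauses {Tp} s"
        )
    return trial.n_steps * step_depth / denom


@dataclass(frozen=True)
class GaitSummary:
    """Mean +/- SD of speed and foot clearances for one trial group."""

    scenario: str
    site: str | None
    n: int
    mean_speed: float
    sd_speed: float
    mean_pfc: float
    sd_pfc: float
    mean_afc: float
    sd_afc: float
    degenerate: bool = False  # single observation: SDs reported as 0


def _depth_for(site: str, step_depths) -> float:
    if isinstance(step_depths, Mapping):
        d = step_depths[site]
        return float(getattr(d, "step_depth", d))
    return float(getattr(step_depths, "step_depth", step_depths))


def summarize(
    trials: Iterable[DescentTrial],
    step_depths,
    by: Sequence[str] = ("scenario", "site"),
    unit: str = "subject",
) -> pd.DataFrame:
    """Group-wise gait summaries (sample SD, n - 1 denominator).

    Parameters
    ----------
    trials : iterable of DescentTrial
    step_depths : float, StaircaseSpec, or mapping site -> either
        Step depth used in the speed formula, per site.
    by : sequence of {"scenario", "site"}
        Grouping keys.
    unit : {"subject", "trial"}
        With ``"subject"`` (default, matching the study's n = 72 sample)
        a subject's repeated trials are averaged before group statistics.

    Returns
    -------
    pandas.DataFrame
        One row per group with columns ``scenario, site, n, mean_speed,
        sd_speed, mean_pfc, sd_pfc, mean_afc, sd_afc, degenerate``.
        Single-observation groups report SD 0 with ``degenerate=True``
        and a warning.
    """
    rows = [
        dict(
            subject_id=t.subject_id,
            scenario=t.scenario,
            site=t.site,
            speed=descent_speed(t, _depth_for(t.site, step_depths)),
            pfc=t.pfc,
            afc=t.afc,
        )
        for t in trials
    ]
    if not rows:
        raise ValueError("no trials to summarize")
    df = pd.DataFrame(rows)
    by = list(by)
    if unit == "subject":
        df = df.groupby(by + ["subject_id"], as_index=False)[
            ["speed", "pfc", "afc"]
        ].mean()
    elif unit != "trial":
        raise ValueError(f"unknown unit {unit!r}")

    out = []
    for key, grp in df.groupby(by):
        key = key if isinstance(key, tuple) else (key,)
        n = len(grp)
        degenerate = n == 1
        if degenerate:
            warnings.warn(
                f"group {dict(zip(by, key))} has a single observation; SD set to 0",
                stacklevel=2,
            )
        rec = dict(zip(by, key))
        rec.setdefault("site", None)
        for col in ("speed", "pfc", "afc"):
            rec[f"mean_{col}"] = float(grp[col].mean())
            rec[f"sd_{col}"] = 0.0 if degenerate else float(grp[col].std(ddof=1))
        rec["n"] = n
        rec["degenerate"] = degenerate
        out.append(rec)
    cols = ["scenario", "site", "n", "mean_speed", "sd_speed",
            "mean_pfc", "sd_pfc", "mean_afc", "sd_afc", "degenerate"]
    return pd.DataFrame(out)[cols].sort_values(by).reset_index(drop=True)


@dataclass(frozen=True)
class SampleStats:
    """A (mean, SD, n) triple for one model parameter."""

    name: str
    mean: float
    sd: float
    n: int
    source: str = ""
    fixed: bool = False


@dataclass(frozen=True)
class ReferencePolicy:
    """Which scenario supplies each reference parameter, and how to round.

    The study takes the target speed from the evacuation scenario (the
    stampede-relevant condition), the posterior foot clearance from the
    paired scenario (closest to crowded descent with observable feet)
    and fixes the initial anterior clearance at zero.  ``decimals`` maps
    parameter names to a rounding applied to mean and SD before use;
    the ``table5`` policy rounds to the published table's print
    precision (so PFC 0.084 becomes 0.08), ``section43`` keeps full
    precision.
    """

    speed_scenario: str = "evacuation"
    pfc_scenario: str = "paired"
    afc_fixed: float = 0.0
    decimals: Mapping[str, int] | None = field(
        default_factory=lambda: {"v": 2, "pfc": 2, "eta": 2, "l": 2, "L": 3}
    )
    name: str = "table5"

    @classmethod
    def table5(cls) -> "ReferencePolicy":
        return cls()

    @classmethod
    def section43(cls) -> "ReferencePolicy":
        return cls(decimals=None, name="section43")

    @classmethod
    def parse(cls, value) -> "ReferencePolicy":
        if isinstance(value, cls):
            return value
        if value in ("table5", "section43"):
            return getattr(cls, value)()
        raise ValueError(f"unknown reference policy {value!r}")

    def round(self, name: str, mean: float, sd: float) -> tuple[float, float]:
        if self.decimals and name in self.decimals:
            nd = self.decimals[name]
            return round(mean, nd), round(sd, nd)
        return mean, sd


def _pool(rows: pd.DataFrame, mean_col: str, sd_col: str) -> tuple[float, float, int]:
    """Exact pooled mean/SD across groups from per-group (n, mean, sd ddof=1)."""
    n = int(rows["n"].sum())
    sx = float((rows["n"] * rows[mean_col]).sum())
    sxx = float(
        ((rows["n"] - 1) * rows[sd_col] ** 2 + rows["n"] * rows[mean_col] ** 2).sum()
    )
    mean = sx / n
    var = (sxx - n * mean**2) / (n - 1) if n > 1 else 0.0
    return mean, math.sqrt(max(var, 0.0)), n


def select_reference_parameters(
    summaries: pd.DataFrame, policy: ReferencePolicy | str = "table5"
) -> dict[str, SampleStats]:
    """Pick the model's v / PFC / AFC references from gait summaries.

    ``summaries`` is the output of :func:`summarize`; rows from several
    sites within a scenario are pooled exactly (from their first two
    moments) before selection.

    Raises
    ------
    KeyError
        If the policy names a scenario absent from the summaries.
    """
    policy = ReferencePolicy.parse(policy)
    out: dict[str, SampleStats] = {}
    for name, scenario, mc, sc in (
        ("v", policy.speed_scenario, "mean_speed", "sd_speed"),
        ("pfc", policy.pfc_scenario, "mean_pfc", "sd_pfc"),
    ):
        rows = summaries[summaries["scenario"] == scenario]
        if rows.empty:
            raise KeyError(
                f"policy requires scenario {scenario!r}, absent from summaries"
            )
        mean, sd, n = _pool(rows, mc, sc)
        mean, sd = policy.round(name, mean, sd)
        out[name] = SampleStats(name, mean, sd, n, source=scenario)
    out["afc"] = SampleStats(
        "afc", policy.afc_fixed, 0.0, out["pfc"].n, source="fixed", fixed=True
    )
    return out
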