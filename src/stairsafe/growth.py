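"""Anthropometric growth trends and service-life projection of the design range.

Children's mean height and foot length drift upward slowly across
calendar time.  Over a building's service life that drift feeds back
into the stair-descent stability model: a taller cohort has a longer
pendulum (via the within-sample regression of l on height) and longer
feet, both of which shift the safe step-depth window.  The projection
advances height and foot length linearly at the fitted national-trend
slopes, recomputes l from the height increment, holds the behavioural
parameters (speed, clearances, eta) fixed, and re-runs the interval
estimation and subrange combination per decade.

The final recommendation couples a future-proofed lower bound (the
projected cohort needs deeper treads) with the present upper bound (the
current cohort must still manage the stride), and prefers the larger
value inside the interval to absorb behavioural deviations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _scipy_stats

from . import reference
from .design import DesignRange, ParameterEstimate, combine_subranges, t_interval
from .stability import UpperRule

__all__ = [
    "GrowthModel",
    "Recommendation",
    "ProjectionResult",
    "fit_trend",
    "default_growth_models",
    "l_from_height",
    "project_params",
    "project_design_range",
    "recommend_range",
]


@dataclass(frozen=True)
class GrowthModel:
    """Linear trend of one anthropometric variable, in cm per year."""

    slope: float
    intercept: float
    r_squared: float
    variable: str = ""
    degenerate: bool = False  # constant series: slope 0, R^2 reported as 0

    def increment_cm(self, years: float) -> float:
        return self.slope * years


def default_growth_models() -> dict[str, GrowthModel]:
    """The study's fitted national trends for height and foot length."""
    return {
        "height": GrowthModel(variable="height", **reference.HEIGHT_TREND),
        "foot_length": GrowthModel(variable="foot_length", **reference.FOOT_LENGTH_TREND),
    }


def fit_trend(time, value, variable: str = "") -> GrowthModel:
    """Ordinary least squares fit of value (cm) against time (years).

    Needs at least 3 points and non-constant time.  A constant series
    is degenerate: slope 0 with R^2 reported as 0 and a flag.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(value, dtype=float)
    if t.size < 3 or t.size != y.size:
        raise ValueError("need at least 3 (time, value) points")
    if np.ptp(t) == 0:
        raise ValueError("time has zero variance")
    if np.ptp(y) == 0:
        warnings.warn(f"constant series for {variable or 'value'}; slope 0, R^2 set to 0",
                      stacklevel=2)
        return GrowthModel(0.0, float(y[0]), 0.0, variable, degenerate=True)
    res = _scipy_stats.linregress(t, y)
    return GrowthModel(float(res.slope), float(res.intercept),
                       float(res.rvalue**2), variable)


def l_from_height(
    height_cm: float,
    coefficients: tuple[float, float] | None = None,
) -> float:
    """Pendulum length (m) from standing height (cm) via the sample regression.

    Default coefficients (0.3484, 33.518) come from the study sample
    (R^2 = 0.73); the regression was fitted on 121-151 cm children and
    extrapolates below ~100 cm, where a warning is emitted.
    """
    if height_cm <= 0:
        raise ValueError(f"height must be positive, got {height_cm}")
    if coefficients is None:
        coefficients = (reference.L_HEIGHT_REGRESSION["slope"],
                        reference.L_HEIGHT_REGRESSION["intercept"])
    slope, intercept = coefficients
    if height_cm < 100:
        warnings.warn(
            f"height {height_cm:.0f} cm is below the fitted range; "
            "l is an extrapolation", stacklevel=2,
        )
    return (slope * height_cm + intercept) / 100.0


def _decades(horizon: float, step: float = 10.0) -> list[float]:
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    ticks = list(np.arange(0.0, horizon, step))
    return [float(t) for t in ticks] + [float(horizon)] if horizon > 0 else [0.0]


def project_params(
    params,
    models: Mapping[str, GrowthModel] | None = None,
    horizon: float = 30.0,
    l_height_slope: float | None = None,
    step: float = 10.0,
):
    """Advance a walker's l and L along the growth trends, per decade.

    ``params`` is a :class:`stairsafe.stability.ModelParams`.  Height
    advances by ``slope * t`` cm; the pendulum length advances by the
    chained increment ``l_height_slope * height_increment / 100`` m
    (applying the l-on-height regression slope so that horizon 0 leaves
    the parameters exactly unchanged); foot length advances by its own
    slope.  Speed and clearances carry no published trend and are held
    fixed.

    Returns a list of ``(years, ModelParams)`` at each decade tick and
    at the horizon.
    """
    if models is None:
        models = default_growth_models()
    if l_height_slope is None:
        l_height_slope = reference.L_HEIGHT_REGRESSION["slope"]
    out = []
    for t in _decades(horizon, step):
        dh_cm = models["height"].increment_cm(t)
        out.append((t, params.model_copy(update={
            "l": params.l + l_height_slope * dh_cm / 100.0,
            "L": params.L + models["foot_length"].increment_cm(t) / 100.0,
        })))
    return out


@dataclass(frozen=True)
class Recommendation:
    """Recommended step-depth interval; the larger value is preferred."""

    low: float
    high: float

    @property
    def preferred(self) -> float:
        return self.high

    def as_tuple(self) -> tuple[float, float]:
        return (self.low, self.high)


def _bounds_of(r) -> tuple[float, float]:
    if hasattr(r, "d_low"):
        return r.d_low, r.d_high
    lo, hi = r
    return float(lo), float(hi)


def recommend_range(current, projected) -> Recommendation:
    """Couple the projected lower bound with the present upper bound.

    ``(projected.d_low, current.d_high)`` — the lower bound must already
    accommodate the taller future cohort, while the upper bound stays
    constrained by today's building occupants.  The larger value in the
    interval is the preferred single design value (it buys margin
    against behavioural deviations).

    Raises
    ------
    ValueError
        If the projected lower bound meets or exceeds the current upper
        bound (no feasible recommendation).
    """
    cur_lo, cur_hi = _bounds_of(current)
    proj_lo, proj_hi = _bounds_of(projected)
    if proj_lo >= cur_hi:
        raise ValueError(
            f"no feasible recommendation: projected lower bound {proj_lo:.3f} "
            f">= current upper bound {cur_hi:.3f}"
        )
    return Recommendation(low=proj_lo, high=cur_hi)


@dataclass(frozen=True)
class ProjectionResult:
    """Design ranges per decade plus the service-life recommendation."""

    horizon: float
    decades: tuple[float, ...]
    tables: dict = field(default_factory=dict)        # years -> parameter rows
    ranges: dict = field(default_factory=dict)        # years -> DesignRange
    recommended: Recommendation | None = None
    drift_per_decade: float = math.nan                # diagnostic, m / 10 yr

    def to_dict(self) -> dict:
        return {
            "horizon": self.horizon,
            "decades": list(self.decades),
            "ranges": {str(k): v.to_dict() for k, v in self.ranges.items()},
            "recommended": asdict(self.recommended) if self.recommended else None,
            "drift_per_decade": self.drift_per_decade,
        }


def project_design_range(
    table: Mapping[str, ParameterEstimate],
    models: Mapping[str, GrowthModel] | None = None,
    horizon: float = 30.0,
    l_height_slope: float | None = None,
    upper_rule: UpperRule = "tread",
    n_range=None,
    step: float = 10.0,
) -> ProjectionResult:
    """Re-derive the design range at each decade of the service life.

    The l and L rows of the parameter table are shifted by the growth
    increments (SDs and n unchanged, intervals recomputed); all other
    rows are held fixed.  The recommendation couples the horizon's lower
    bound with today's upper bound.  ``drift_per_decade`` reports the
    mean per-decade shift of the lower bound as a diagnostic.
    """
    if models is None:
        models = default_growth_models()
    if l_height_slope is None:
        l_height_slope = reference.L_HEIGHT_REGRESSION["slope"]
    decades = _decades(horizon, step)
    tables: dict[float, dict] = {}
    ranges: dict[float, DesignRange] = {}
    for t in decades:
        dh_cm = models["height"].increment_cm(t)
        shifted = dict(table)
        for name, dm in (("l", l_height_slope * dh_cm / 100.0),
                         ("L", models["foot_length"].increment_cm(t) / 100.0)):
            est = table[name]
            if est.n >= 2:
                shifted[name] = ParameterEstimate.from_sample(
                    name, est.mean + dm, est.sd, est.n, est.alpha, notes=est.notes
                )
            else:
                shifted[name] = ParameterEstimate(
                    name=name, mean=est.mean + dm, sd=est.sd, n=est.n,
                    alpha=est.alpha, notes=est.notes,
                )
        tables[t] = shifted
        ranges[t] = combine_subranges(shifted, n_range=n_range, upper_rule=upper_rule)
    current, final = ranges[decades[0]], ranges[decades[-1]]
    rec = recommend_range(current, final)
    drift = (
        (final.d_low - current.d_low) / (horizon / 10.0)
        if horizon > 0 else math.nan
    )
    return ProjectionResult(
        horizon=horizon, decades=tuple(decades), tables=tables, ranges=ranges,
        recommended=rec, drift_per_decade=drift,
    )
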