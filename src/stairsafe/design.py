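"""Interval estimation and the subrange combination behind the design range.

Each model parameter (PFC, eta, v, l, L) is treated as a normal-population
sample of size n; its two-sided Student-t interval is

    x_bar +/- t_{alpha/2}(n - 1) * s / sqrt(n).

The design range of step depth is then combined one parameter at a time:
sweep each parameter over its interval endpoints (and the flight length N
over its integer range) with the others held at their sample means,
evaluate the step-depth lower and upper bounds over the N range, and take

    d_low  = max over all recorded lower-bound values,
    d_high = min over all recorded upper-bound values.

The combination's upper bound defaults to the ``tread`` reading of the
reach constraint, ``d <= (PFC + L + N*dcom) / N``: the published
per-parameter design subranges reproduce to print precision under that
arithmetic (e.g. the v row's 0.291/0.302 and the l row's 0.293/0.300 at
N = 7), whereas the alternative ``stride`` reading divides by N - 1 and
cannot produce them.  Both rules are available.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

from scipy import stats

from . import reference
from .stability import UpperRule, delta_com, sdp_lower_bound, sdp_upper_bound

__all__ = [
    "ParameterEstimate",
    "DesignRange",
    "InfeasibleDesignError",
    "t_interval",
    "parameter_table",
    "reference_parameter_table",
    "combine_subranges",
]

#: Parameters swept by the combination (L enters the upper bound at its
#: sample mean only, matching the published table's rows).
SWEPT_PARAMETERS = ("pfc", "eta", "v", "l", "N")


class InfeasibleDesignError(ValueError):
    """Raised when the combined design range is empty (d_low >= d_high)."""


def t_interval(mean: float, sd: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Two-sided Student-t confidence interval for a normal mean.

    Full-precision endpoints; display rounding (3 decimals in reports)
    is left to the callers.

    Raises
    ------
    ValueError
        If ``n < 2``, ``sd < 0`` or alpha is not in (0, 1).
    """
    if n < 2:
        raise ValueError(f"need n >= 2 observations, got {n}")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    half = float(stats.t.ppf(1 - alpha / 2, n - 1)) * sd / math.sqrt(n)
    return float(mean - half), float(mean + half)


@dataclass(frozen=True)
class ParameterEstimate:
    """Sample estimate of one model parameter with its confidence interval.

    For the integer flight length N no interval is estimated;
    ``fixed_range`` carries the designed range of consecutive steps.
    """

    name: str
    mean: float
    sd: float = 0.0
    n: int = 0
    alpha: float = reference.ALPHA
    ci_low: float = math.nan
    ci_high: float = math.nan
    fixed_range: tuple[int, int] | None = None
    notes: tuple[str, ...] = ()

    @classmethod
    def from_sample(cls, name: str, mean: float, sd: float, n: int,
                    alpha: float = reference.ALPHA,
                    notes: tuple[str, ...] = ()) -> "ParameterEstimate":
        lo, hi = t_interval(mean, sd, n, alpha)
        return cls(name=name, mean=mean, sd=sd, n=n, alpha=alpha,
                   ci_low=lo, ci_high=hi, notes=notes)


def parameter_table(
    samples: Mapping[str, tuple[float, float, int]],
    alpha: float = reference.ALPHA,
    n_range: tuple[int, int] = reference.STEP_RANGE,
) -> dict[str, ParameterEstimate]:
    """Build the parameter table feeding the design-range combination.

    Parameters
    ----------
    samples : mapping
        ``{"pfc" | "eta" | "v" | "l" | "L": (mean, sd, n)}`` — all five
        are required.
    alpha : float
        Two-sided confidence level.
    n_range : (int, int)
        Inclusive range of consecutive steps, carried as a fixed range.

    Notes
    -----
    The recomputed v interval is compared against the published one,
    (0.711, 0.745), which does not follow from x_bar +/- t*s/sqrt(n)
    applied to 0.88 +/- 0.08 with n = 72; a discrepancy note is attached
    to the v row whenever the recomputed interval disagrees with it.
    """
    missing = [p for p in ("pfc", "eta", "v", "l", "L") if p not in samples]
    if missing:
        raise KeyError(f"missing required parameters: {missing}")
    table: dict[str, ParameterEstimate] = {}
    for name in ("pfc", "eta", "v", "l", "L"):
        mean, sd, n = samples[name]
        table[name] = ParameterEstimate.from_sample(name, mean, sd, n, alpha)
    pub_v = reference.PUBLISHED_SUBRANGES["v"]["ci"]
    v = table["v"]
    if abs(v.ci_low - pub_v[0]) > 0.005 or abs(v.ci_high - pub_v[1]) > 0.005:
        table["v"] = ParameterEstimate(
            **{**asdict(v), "notes": v.notes + (
                f"recomputed interval ({v.ci_low:.3f}, {v.ci_high:.3f}) differs "
                f"from the published ({pub_v[0]:.3f}, {pub_v[1]:.3f}), which is "
                "inconsistent with the t-formula at the stated mean/SD/n",
            )}
        )
    lo_n, hi_n = int(n_range[0]), int(n_range[1])
    if lo_n > hi_n:
        raise ValueError(f"empty N range ({lo_n}, {hi_n})")
    table["N"] = ParameterEstimate(name="N", mean=(lo_n + hi_n) / 2,
                                   fixed_range=(lo_n, hi_n))
    return table


def reference_parameter_table(alpha: float = reference.ALPHA) -> dict[str, ParameterEstimate]:
    """Parameter table at the study's published sample means and SDs (n = 72)."""
    samples = {
        name: (mean, sd, reference.N_SUBJECTS)
        for name, (mean, sd) in reference.SAMPLE_MEANS.items()
    }
    return parameter_table(samples, alpha=alpha)


@dataclass(frozen=True)
class DesignRange:
    """Safe step-depth design window with per-parameter provenance.

    ``subranges`` maps each swept parameter to the (min, max) of the
    lower and upper depth bounds as that parameter sweeps its interval;
    ``provenance`` records the rule, the binding parameter/endpoint for
    each side, and residuals against the published totals.
    """

    d_low: float
    d_high: float
    subranges: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def bounds(self) -> tuple[float, float]:
        return self.d_low, self.d_high

    def to_dict(self) -> dict:
        return asdict(self)


def _sweep_points(table: Mapping[str, ParameterEstimate], param: str) -> list[float]:
    est = table[param]
    if math.isnan(est.ci_low) or est.sd == 0:
        return [est.mean]
    return [est.ci_low, est.ci_high]


def combine_subranges(
    table: Mapping[str, ParameterEstimate],
    n_range: Iterable[int] | None = None,
    upper_rule: UpperRule = "tread",
    factorial: bool = False,
    g: float = 9.81,
) -> DesignRange:
    """Combine per-parameter subranges into the step-depth design window.

    One-at-a-time sweeps by default (each of pfc, eta, v, l over its CI
    endpoints with the others at sample means; N over its integer
    range); ``factorial=True`` sweeps the full cross product of
    endpoints instead, which is strictly more conservative.

    Raises
    ------
    InfeasibleDesignError
        If the maximum of the lower-bound values meets or exceeds the
        minimum of the upper-bound values.
    """
    for required in ("pfc", "eta", "v", "l", "L"):
        if required not in table:
            raise KeyError(f"parameter table lacks {required!r}")
    if n_range is None:
        fr = table["N"].fixed_range if "N" in table else reference.STEP_RANGE
        n_range = range(fr[0], fr[1] + 1)
    ns = sorted(set(int(n) for n in n_range))
    if not ns or ns[0] < 2:
        raise ValueError("n_range must contain integers >= 2")

    means = {p: table[p].mean for p in ("pfc", "eta", "v", "l", "L")}

    def bounds_at(pt: Mapping[str, float], n: int) -> tuple[float, float]:
        dcom = delta_com(pt["v"], pt["l"], g)
        return (
            sdp_lower_bound(pt["pfc"], pt["eta"], dcom, n),
            sdp_upper_bound(pt["pfc"], means["L"], dcom, n, rule=upper_rule),
        )

    subranges: dict[str, dict[str, tuple[float, float]]] = {}
    best_low = (-math.inf, None)
    best_high = (math.inf, None)

    def record(param: str, lows: list, highs: list):
        subranges[param] = {
            "lower": (min(v for v, _ in lows), max(v for v, _ in lows)),
            "upper": (min(v for v, _ in highs), max(v for v, _ in highs)),
        }

    if factorial:
        endpoint_sets = {p: _sweep_points(table, p) for p in ("pfc", "eta", "v", "l")}
        lows, highs = [], []
        for combo in itertools.product(*endpoint_sets.values()):
            pt = dict(zip(endpoint_sets, combo))
            for n in ns:
                lo, hi = bounds_at({**means, **pt}, n)
                tag = {**pt, "N": n}
                lows.append((lo, tag))
                highs.append((hi, tag))
        record("factorial", lows, highs)
        all_lows, all_highs = lows, highs
    else:
        all_lows, all_highs = [], []
        for param in SWEPT_PARAMETERS:
            points = [means] if param == "N" else [
                {**means, param: val} for val in _sweep_points(table, param)
            ]
            lows, highs = [], []
            for pt in points:
                for n in ns:
                    lo, hi = bounds_at(pt, n)
                    tag = {"param": param, "value": pt.get(param, "mean"), "N": n}
                    lows.append((lo, tag))
                    highs.append((hi, tag))
            record(param, lows, highs)
            all_lows += lows
            all_highs += highs

    for v, tag in all_lows:
        if v > best_low[0]:
            best_low = (v, tag)
    for v, tag in all_highs:
        if v < best_high[0]:
            best_high = (v, tag)

    d_low, d_high = best_low[0], best_high[0]
    pub_lo, pub_hi = reference.PUBLISHED_DESIGN_RANGE
    provenance = {
        "upper_rule": upper_rule,
        "n_range": (ns[0], ns[-1]),
        "factorial": factorial,
        "g": g,
        "binding_lower": best_low[1],
        "binding_upper": best_high[1],
        "published_total": reference.PUBLISHED_DESIGN_RANGE,
        "residual_low": d_low - pub_lo,
        "residual_high": d_high - pub_hi,
    }
    if d_low >= d_high:
        raise InfeasibleDesignError(
            f"infeasible combination: d_low {d_low:.4f} >= d_high {d_high:.4f}"
        )
    return DesignRange(d_low=d_low, d_high=d_high,
                       subranges=subranges, provenance=provenance)
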