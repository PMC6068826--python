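"""Inverted-pendulum dynamic-stability model of stair descent.

A walker descending stairs is modelled as a single-mass inverted pendulum
pivoting about the ankle of the stance foot.  The dynamic-stability
reference point is the extrapolated centre of mass (XCoM): the vertical
CoM projection plus the horizontal velocity divided by the pendulum
eigenfrequency ``omega0 = sqrt(g / l)``.  Each step therefore carries the
projected CoM an anterior drift of

    ``delta_com = v * sqrt(l / g)``   (metres)

ahead of where the stance foot was planted.  Postural risk is recognised
when the XCoM passes the anterior edge of the base of support (the tread
edge); the usable support is bounded in front by the critical centre of
pressure at the midfoot/forefoot junction, a distance ``eta`` from the
heel and ``L - eta`` from the toes.

Writing the cumulative positions along a flight of ``N`` steps of depth
``d`` (heel planted a posterior foot clearance ``pfc`` from each riser)
gives two closed-form constraints on ``d``:

* minimum depth — after ``N - 1`` drifts the critical CoP must still be
  on the ``N``-th tread::

      pfc + eta + (N - 1) * delta_com <= N * d

* maximum depth — the step-by-step strategy must remain viable, i.e. the
  toes must still reach the far tread edge after ``N`` drifts.  Two
  published readings of this inequality exist and both are implemented
  (see :func:`sdp_upper_bound`):

      ``stride``:  (N - 1) * d <= pfc + L + N * delta_com
      ``tread``:        N * d <= pfc + L + N * delta_com

:func:`simulate_descent` is a deliberately naive step-by-step oracle for
the same geometry, kept free of the closed forms so the two routes can be
cross-checked against each other.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import reference

__all__ = [
    "StaircaseSpec",
    "ModelParams",
    "StabilityState",
    "StaircaseAudit",
    "UpperRule",
    "delta_com",
    "sdp_lower_bound",
    "sdp_upper_bound",
    "sdp_range",
    "simulate_descent",
    "audit_staircase",
    "study_sites",
    "read_staircases_csv",
    "write_staircases_csv",
]

UpperRule = Literal["stride", "tread"]

#: Default gravitational acceleration, m/s^2.
G_DEFAULT = 9.81

#: Tolerance (degrees) for a declared inclination against arctan(h/d).
INCLINE_TOL_DEG = 0.05


class StaircaseSpec(BaseModel):
    """Geometry of one straight flight of stairs.

    Parameters
    ----------
    riser_height : float
        Vertical rise of one step, m.
    step_depth : float
        Horizontal run (going) of one tread, m.
    step_width : float
        Lateral width of the flight, m.
    n_steps : int
        Number of steps in the flight (>= 2).
    incline_deg : float, optional
        Inclination angle in degrees.  Computed as ``arctan(h/d)`` when
        omitted; when given it must agree with the geometry to 0.05 deg.
    """

    model_config = dict(frozen=True)

    name: str = "staircase"
    riser_height: float = Field(gt=0)
    step_depth: float = Field(gt=0)
    step_width: float = Field(gt=0)
    n_steps: int = Field(ge=2)
    incline_deg: float | None = None

    @model_validator(mode="after")
    def _check_incline(self) -> "StaircaseSpec":
        geom = math.degrees(math.atan2(self.riser_height, self.step_depth))
        if self.incline_deg is None:
            object.__setattr__(self, "incline_deg", geom)
        elif abs(self.incline_deg - geom) > INCLINE_TOL_DEG:
            raise ValueError(
                f"incline_deg={self.incline_deg:.2f} inconsistent with "
                f"arctan(h/d)={geom:.2f} for {self.name!r}"
            )
        return self


class ModelParams(BaseModel):
    """Pendulum and foot-geometry parameters of one (typical) walker.

    ``v`` is the horizontal CoM speed (m/s); ``l`` the CoM-to-ankle
    pendulum length (m); ``L`` the foot length (m); ``eta`` the
    heel-to-critical-CoP distance (m, ``0 <= eta <= L``); ``pfc`` the
    posterior foot clearance (m); ``afc`` the anterior foot clearance
    used only as an initial-state indicator (m, default 0, may be
    negative when the toes overhang); ``g`` gravity (m/s^2).
    """

    model_config = dict(frozen=True)

    v: float = Field(ge=0)
    l: float = Field(gt=0)
    L: float = Field(gt=0)
    eta: float = Field(ge=0)
    pfc: float = Field(ge=0)
    afc: float = 0.0
    g: float = Field(default=G_DEFAULT, gt=0)

    @model_validator(mode="after")
    def _check_eta(self) -> "ModelParams":
        if self.eta > self.L:
            raise ValueError(f"eta={self.eta} exceeds foot length L={self.L}")
        return self

    @property
    def delta_com(self) -> float:
        return delta_com(self.v, self.l, self.g)


@dataclass(frozen=True)
class StabilityState:
    """Per-step stability snapshot in the cumulative (flight) frame.

    ``cop_position`` is the critical CoP after ``step_index - 1`` drifts,
    measured from the first riser; ``bos_edge`` is the anterior edge of
    the ``step_index``-th tread (= ``step_index * d``); ``margin`` is
    their difference (negative = fall risk); ``cop_from_riser`` maps the
    CoP back into the current step's own frame.  ``over_reach`` flags a
    tread so deep the toes can no longer reach the required edge.
    """

    step_index: int
    cop_position: float
    bos_edge: float
    margin: float
    cop_from_riser: float
    risky: bool
    over_reach: bool


def delta_com(v: float, l: float, g: float = G_DEFAULT) -> float:
    """Anterior drift of the projected CoM over one step, ``v * sqrt(l/g)``.

    Equivalent to the standard XCoM offset ``v / omega0`` with
    ``omega0 = sqrt(g / l)``.

    Parameters
    ----------
    v : float
        Horizontal CoM speed, m/s (>= 0).
    l : float
        Pendulum length (CoM to ankle), m (> 0).
    g : float
        Gravity, m/s^2 (> 0).

    Returns
    -------
    float
        Drift in metres.
    """
    if l <= 0:
        raise ValueError(f"pendulum length must be positive, got {l}")
    if g <= 0:
        raise ValueError(f"gravity must be positive, got {g}")
    if v < 0:
        raise ValueError(f"speed must be non-negative, got {v}")
    return v * math.sqrt(l / g)


def sdp_lower_bound(pfc: float, eta: float, dcom: float, n: int) -> float:
    """Minimum safe step depth for an ``n``-step flight.

    Solves ``pfc + eta + (n - 1) * dcom <= n * d`` for ``d``:
    ``(pfc + eta + (n - 1) * dcom) / n``.  Equality (CoP exactly at the
    tread edge) is safe.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return (pfc + eta + (n - 1) * dcom) / n


def sdp_upper_bound(
    pfc: float, L: float, dcom: float, n: int, rule: UpperRule = "stride"
) -> float:
    """Maximum step depth keeping the step-by-step strategy viable.

    Two readings of the reach constraint are in circulation and both are
    implemented:

    * ``rule="stride"`` (default): ``(n - 1) * d <= pfc + L + n * dcom``,
      i.e. ``d <= (pfc + L + n * dcom) / (n - 1)`` — after ``n`` drifts
      the toes still reach past the edge of the ``(n - 1)``-th step.
    * ``rule="tread"``: ``n * d <= pfc + L + n * dcom``, i.e.
      ``d <= (pfc + L) / n + dcom`` — the toes reach the edge of the
      ``n``-th tread itself.  This is the arithmetic under which the
      published per-parameter design subranges reproduce to print
      precision, so the design-range combination defaults to it (see
      :func:`stairsafe.design.combine_subranges`).
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if rule == "stride":
        return (pfc + L + n * dcom) / (n - 1)
    if rule == "tread":
        return (pfc + L + n * dcom) / n
    raise ValueError(f"unknown upper-bound rule {rule!r}")


def sdp_range(
    params: ModelParams, n: int, rule: UpperRule = "stride"
) -> tuple[float, float]:
    """Closed-form safe design range ``(d_min, d_max)`` for an ``n``-step flight.

    Raises
    ------
    ValueError
        If the parameters make the range infeasible (lower >= upper).
    """
    dcom = params.delta_com
    lo = sdp_lower_bound(params.pfc, params.eta, dcom, n)
    hi = sdp_upper_bound(params.pfc, params.L, dcom, n, rule=rule)
    if lo >= hi:
        raise ValueError(
            f"infeasible parameters: lower bound {lo:.4f} >= upper bound {hi:.4f}"
        )
    return lo, hi


def simulate_descent(
    params: ModelParams,
    staircase: StaircaseSpec,
    rule: UpperRule = "stride",
) -> list[StabilityState]:
    """Step-by-step descent oracle.

    Walks the flight one step at a time in the cumulative frame: the
    critical CoP starts at ``pfc + eta`` from the first riser and
    advances ``delta_com`` per step.  State ``k`` is ``risky`` when the
    CoP has passed the ``k``-th tread edge (``pfc + eta + (k-1)*dcom >
    k*d``; equality safe) and ``over_reach`` when the tread is too deep
    for the toes to reach the edge required by ``rule``.

    This function intentionally repeats the geometry with positions and
    comparisons rather than reusing the closed-form bounds, so it can
    serve as an independent cross-check of :func:`sdp_range`.
    """
    d = staircase.step_depth
    dcom = params.delta_com
    reach_start = params.pfc + params.L  # toes' cumulative start position
    states: list[StabilityState] = []
    cop = params.pfc + params.eta  # cumulative CoP before any drift
    for k in range(1, staircase.n_steps + 1):
        edge = k * d
        margin = edge - cop
        toes = reach_start + k * dcom
        required = (k - 1) * d if rule == "stride" else k * d
        states.append(
            StabilityState(
                step_index=k,
                cop_position=cop,
                bos_edge=edge,
                margin=margin,
                cop_from_riser=cop - (k - 1) * d,
                risky=cop > edge,
                over_reach=required > toes,
            )
        )
        cop += dcom
    return states


@dataclass(frozen=True)
class StaircaseAudit:
    """Safety verdict for one staircase over a range of flight lengths."""

    staircase: dict
    params: dict
    rule: str
    per_n: dict[int, dict]
    d_low: float
    d_high: float
    safe: bool
    violations: tuple[str, ...]

    def to_json(self, **kwargs) -> str:
        payload = asdict(self)
        payload["per_n"] = {str(k): v for k, v in self.per_n.items()}
        return json.dumps(payload, sort_keys=True, **kwargs)

    def render_text(self) -> str:
        lines = [
            f"Staircase audit: {self.staircase['name']} "
            f"(d = {self.staircase['step_depth']:.3f} m, "
            f"{self.staircase['n_steps']} steps)",
            f"  rule: {self.rule}; flight lengths N = "
            f"{min(self.per_n)}..{max(self.per_n)}",
        ]
        for n, row in sorted(self.per_n.items()):
            lines.append(
                f"  N={n:>2}: safe depth in [{row['lower']:.3f}, "
                f"{row['upper']:.3f}] m -> {'ok' if row['safe'] else 'VIOLATED'}"
            )
        lines.append(
            f"  overall safe window: [{self.d_low:.3f}, {self.d_high:.3f}] m"
        )
        verdict = "SAFE" if self.safe else "UNSAFE: " + "; ".join(self.violations)
        lines.append(f"  verdict: {verdict}")
        return "\n".join(lines)


def audit_staircase(
    staircase: StaircaseSpec,
    params: ModelParams,
    n_range: Iterable[int] | None = None,
    rule: UpperRule = "stride",
) -> StaircaseAudit:
    """Check a staircase's step depth against the model bounds per flight length.

    ``n_range`` defaults to the study's 7..12 consecutive steps, clipped
    to the staircase's own step count.  The overall verdict is safe iff
    the depth lies in ``[max_n lower(n), min_n upper(n)]`` (boundary
    inclusive).
    """
    if n_range is None:
        lo_n, hi_n = reference.STEP_RANGE
        n_range = range(lo_n, min(hi_n, staircase.n_steps) + 1)
    ns = sorted(set(int(n) for n in n_range))
    if not ns:
        raise ValueError("empty n_range")
    if ns[0] < 2 or ns[-1] > staircase.n_steps:
        raise ValueError(
            f"n_range must lie within [2, {staircase.n_steps}], got {ns[0]}..{ns[-1]}"
        )
    d = staircase.step_depth
    dcom = params.delta_com
    per_n = {}
    violations = []
    for n in ns:
        lo = sdp_lower_bound(params.pfc, params.eta, dcom, n)
        hi = sdp_upper_bound(params.pfc, params.L, dcom, n, rule=rule)
        safe = lo <= d <= hi
        per_n[n] = dict(lower=lo, upper=hi, safe=safe)
        if d < lo:
            violations.append(
                f"N={n}: d={d:.3f} < minimum {lo:.3f} (XCoM passes the tread edge)"
            )
        elif d > hi:
            violations.append(
                f"N={n}: d={d:.3f} > maximum {hi:.3f} (step-by-step reach exceeded)"
            )
    d_low = max(row["lower"] for row in per_n.values())
    d_high = min(row["upper"] for row in per_n.values())
    return StaircaseAudit(
        staircase=staircase.model_dump(),
        params=params.model_dump(),
        rule=rule,
        per_n=per_n,
        d_low=d_low,
        d_high=d_high,
        safe=d_low <= d <= d_high,
        violations=tuple(violations),
    )


# ---------------------------------------------------------------------------
# Study staircases and tabular IO

def study_sites() -> dict[str, StaircaseSpec]:
    """The three experiment-site staircases as :class:`StaircaseSpec`."""
    return {
        name: StaircaseSpec(
            name=name,
            riser_height=row["riser_height"],
            step_depth=row["step_depth"],
            step_width=row["step_width"],
            incline_deg=row["incline_deg"],
            n_steps=row["n_steps"],
        )
        for name, row in reference.SITE_GEOMETRY.items()
    }


_CSV_COLS = ["name", "riser_height", "step_depth", "step_width", "incline_deg", "n_steps"]


def write_staircases_csv(specs: Sequence[StaircaseSpec], path: str | Path) -> None:
    pd.DataFrame([s.model_dump() for s in specs])[_CSV_COLS].to_csv(path, index=False)


def read_staircases_csv(path: str | Path) -> list[StaircaseSpec]:
    df = pd.read_csv(path)
    return [StaircaseSpec(**row) for row in df.to_dict("records")]
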