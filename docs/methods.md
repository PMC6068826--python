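# Methods

## Model and assumptions

Stair descent is treated as a sequence of discrete single-support
states: the whole body mass balances on one stance ankle, modelled as an
inverted pendulum of length `l` (CoM to ankle). Stability is assessed
with the extrapolated centre of mass, `XCoM = pCoM + v/ω₀` with
`ω₀ = √(g/l)`, so one step carries the projected CoM an anterior drift

    ΔCoM = v·√(l/g)    [m]

The base of support on a tread is bounded in front not by the toes but
by the critical centre of pressure at the midfoot/forefoot junction — a
distance `η` from the heel, `L − η` from the toes. With the heel planted
a posterior foot clearance `PFC` behind each riser, writing cumulative
positions along an `N`-step flight of depth `d` gives:

* **minimum depth** — after `N − 1` drifts the critical CoP must still
  be on the `N`-th tread: `PFC + η + (N−1)·ΔCoM ≤ N·d`, i.e.
  `d ≥ (PFC + η + (N−1)·ΔCoM)/N`. Equality (CoP exactly at the edge) is
  safe, matching the inequality's `≤`.
* **maximum depth** — the "step-by-step" strategy must stay viable: the
  toes (at `PFC + L` plus `N` drifts, cumulatively) must still reach the
  far tread edge. Two readings exist, and the package implements both:
  - `stride`: `(N−1)·d ≤ PFC + L + N·ΔCoM` → `d ≤ (PFC+L+N·ΔCoM)/(N−1)`
  - `tread`: `N·d ≤ PFC + L + N·ΔCoM` → `d ≤ (PFC+L)/N + ΔCoM`

Anterior foot clearance (AFC, negative when the toes overhang) is an
initial-state indicator only, fixed at 0 in the model; it never enters
the bounds. Simplifications: no double-support phase, no handrail
forces, no full-body dynamics, no within-flight speed modulation.

### Why two upper-bound rules, and which is used where

The published analysis this package reanalyses typesets the reach
constraint in the `stride` form, but its printed design-range table is
arithmetically consistent only with the `tread` form: evaluating
`(PFC+L)/N + ΔCoM` at `N = 7` reproduces the printed per-parameter
upper-bound values to print precision (e.g. 0.291/0.302 for the speed
row, 0.293/0.300 for the pendulum-length row, 0.296 for the clearance
rows), which the `stride` form cannot produce at any `N` in range.
Accordingly:

* `stability.sdp_upper_bound`, `sdp_range`, `simulate_descent` and
  `audit_staircase` default to `stride` — the typeset inequality, the
  more permissive and therefore structurally "audit-shaped" bound;
* `design.combine_subranges` (and everything downstream: projection,
  pipeline, reports) defaults to `tread` — the arithmetic the published
  design-range table demonstrably used, hence the right default for
  reproducing and extending that table.

Every entry point takes a `rule=`/`upper_rule=` argument, so either
convention can be enforced end to end.

## Interval estimation and the subrange combination

Each continuous parameter (PFC, η, v, l, L) is a normal-population
sample of size `n = 72`; its two-sided interval is
`x̄ ± t_{α/2}(n−1)·s/√n` with `α = 0.05` (scipy's Student-t inverse CDF;
quantile accuracy far exceeds the 1e−6 requirement). Internally all
arithmetic is full precision; 3-decimal (metres) / 2-decimal (degrees)
rounding is display-only.

The combination sweeps one parameter at a time over its interval
endpoints — others at sample means, `L` entering the upper bound at its
mean only, `N` sweeping the integers 7..12 — records each parameter's
(min, max) per bound, and sets

    d_low  = max of all lower-bound values
    d_high = min of all upper-bound values

A full-factorial sweep over all endpoint combinations is available
(`factorial=True`) and is strictly more conservative. Widening any
interval can only widen the per-parameter subranges and shrink the
combined window — the conservative direction, verified by test. An empty
window raises `InfeasibleDesignError`.

### Known discrepancies in the published table

These are reproduced as *reported discrepancies*, not fitted:

* the published v interval (0.711, 0.745) does not follow from
  0.88 ± 0.08 at n = 72 (the formula gives (0.861, 0.899)); the package
  recomputes and flags the difference in reports;
* the published total maximum 0.282 is smaller than the minimum of the
  published per-row maxima (0.291) and is not reconstructible from the
  printed inputs under any single rule; the clearance and flight-length
  rows' maxima (0.330/0.329) match the `tread` arithmetic only at
  `N = 4`, outside the stated 7..12 sweep;
* at the published inputs the package computes a window of
  (0.2526, 0.2728) against published totals (0.250, 0.282); the
  residuals (+0.0026, −0.0092) ride along in `DesignRange.provenance`.

## Gait statistics

Speed is the pause-corrected `v = N·d/(T − Tp)`. Trials store events as
`(step_index, crossing_time)` with a step-0 row at `t = 0` marking the
departure from the top landing, so `N` steps have exactly `N` dwell
intervals: the formula round-trips exactly on pause-free synthetic
trials, and a certain pause on every step lengthens `T` by exactly
`N·pause`. Descents alone or in pairs are continuous by definition
(`Tp = 0`); only evacuation trials are pause-corrected.

Pauses are not operationalised in the source analysis; here a pause is
the excess of a step dwell over a 0.8 s threshold (about the mean dwell
plus two SDs at typical speeds). Threshold detection is biased by
construction — it recovers `pause + dwell − threshold` — so pipeline
statistics use the ground-truth pause time recorded on synthetic trials;
`detect_pauses` serves event-only data.

Group summaries default to subject level (a subject's two trials
averaged first), matching the study's n = 72 inference; note this
shrinks the dispersion of subject means relative to the trial-level SD
(by ~√2 when trial speeds are drawn independently), which is one reason
reproduction of the published table goes through the printed reference
values rather than through a synthetic cohort. The reference policy
`table5` rounds selected means/SDs to the published table's print
precision (PFC 0.084 → 0.08); `section43` keeps full precision.

## Synthetic cohort generator

The generator emulates the study conditions: 12 students per grade,
grades 1–6; grade-stratified normal anthropometrics from the published
table (heights read as ×10 cm — the table prints "0.121 ± 5.3" m — and
the implausible grade-5 foot-length SD of 0.17 m replaced by 0.017 m);
η = 0.11 ± 0.01 m redrawn until η < L; scenario speeds alone
0.91 ± 0.13, paired 0.82 ± 0.10 (pooled by eye from the three printed
site values), evacuation 0.88 ± 0.08 m/s; PFC 0.084 ± 0.02 m; AFC
−0.02 ± 0.02 m; two trials per subject; subjects assigned to the three
site staircases in contiguous blocks of 24. Pauses occur only in
evacuation, each step independently with probability 0.3, lasting
1.5 ± 0.4 s — values chosen once as plausible for crowd-constrained
descent, since the source reports none. Lengths and speeds are
truncated-normal above zero (scipy `truncnorm`); AFC is plain normal
because negative values are meaningful.

What the generator does **not** emulate: within-subject speed
persistence across trials, site-specific speed differences, gait
maturation within a grade, measurement error of the video extraction,
and any non-normality of real anthropometrics. Passing tests therefore
demonstrate the pipeline's statistical machinery and the model's
internal consistency, not field validity of the data model.

## Growth projection

Mean height and foot length advance linearly at the published national
trends (0.4359 and 0.1629 cm/yr; `fit_trend` exists to refit
user-supplied two-column year/value series via OLS). The pendulum length
follows height through the within-sample regression
`l = (0.3484·h_cm + 33.518)/100`, applied in increment form
(`Δl = 0.3484·Δh/100`) so a zero horizon is exactly the identity. Speed
and clearances carry no published trend and are held fixed
(configurable). The design range is recombined per decade; the
recommendation couples the horizon's lower bound with today's upper
bound and prefers the larger value in the interval. The lower bound's
drift (~2.2 mm/decade at default settings) is reported as a diagnostic
rather than enforced, because the source's own figures for it ("0.001 m
per ten years" vs a 0.008 m shift over 30 years) are mutually
inconsistent.

## Numerical and design choices

* g defaults to 9.81 m/s², configurable everywhere ΔCoM is formed.
* Tie-breaks: boundary equality is safe in every inequality.
* The step-by-step simulator (`simulate_descent`) recomputes positions
  and comparisons independently of the closed forms; a 10,000-case
  randomized equivalence test keeps the two routes honest.
* Determinism: one seed drives cohort and trials (per-site/scenario
  streams derived via `SeedSequence`-style keyed `default_rng`); JSON is
  written with sorted keys and no timestamps, so identical seed + config
  ⇒ byte-identical artifacts.
* Config validation collects *all* violations (pydantic field errors
  plus cross-field checks) before failing.
* Problem sizes in the test suite (cohorts of tens to 10,000 draws,
  5,000-replicate coverage, 10,000-case equivalence) were chosen to make
  Monte-Carlo tolerances comfortably resolvable while keeping the whole
  suite in seconds.

## Limitations

The model is planar and quasi-static per step; it ignores handrails,
double support, step-surface friction and inter-person contact forces —
the very forces that turn a single fall into a stampede are outside its
scope. The design window speaks to geometry's contribution to the first
fall. The published totals it is compared against embed documented
internal inconsistencies, so agreement is reported with residuals rather
than asserted exactly.
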