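# stairsafe

Crowd stampedes on school staircases typically begin with one child
falling forward on a tread that is too shallow for the way children
actually descend stairs. `stairsafe` turns per-student gait observations
— descent speed, foot clearances, body geometry — into a statistically
derived, growth-adjusted **safe design range for stair step depth** in
primary schools. It is a library for researchers in gait biomechanics
and building-safety engineering, with a thin CLI for one-off staircase
audits.

## The model

Stair descent is modelled as an inverted pendulum on the stance ankle.
The dynamic-stability reference is the extrapolated centre of mass
(XCoM): the CoM projection plus velocity over the pendulum
eigenfrequency ω₀ = √(g/l). Each step advances the projected CoM by

    ΔCoM = v·√(l/g)

where v is the horizontal CoM speed and l the CoM–ankle distance. With a
posterior foot clearance *PFC* (heel to riser), foot length *L*, and the
critical centre of pressure at the midfoot/forefoot junction (η from the
heel), descending N steps of depth d is safe when

    PFC + η + (N−1)·ΔCoM ≤ N·d          (minimum depth)
    d ≤ (PFC + L + N·ΔCoM) / N          (maximum depth, "tread" rule)

The upper bound also ships in the "stride" reading, dividing by N−1;
`docs/methods.md` explains why both exist and when each is used.
Parameter uncertainty enters through two-sided Student-t intervals
(x̄ ± t_{α/2}(n−1)·s/√n, α = 0.05, n = 72); each parameter sweeps its
interval one at a time, N sweeps 7..12, and the design window is the
intersection of all resulting bounds. A linear growth projection
(height ≈ 0.44 cm/yr, foot length ≈ 0.16 cm/yr over a 30-year service
life) then future-proofs the lower bound.

## Worked example

```python
from stairsafe import combine_subranges, project_design_range, reference_parameter_table

table = reference_parameter_table()   # published sample values, n = 72
dr = combine_subranges(table)
print(f"design range: [{dr.d_low:.3f}, {dr.d_high:.3f}] m")

proj = project_design_range(table, horizon=30)
rec = proj.recommended
print(f"recommended step depth: [{rec.low:.3f}, {rec.high:.3f}] m, "
      f"prefer {rec.preferred:.3f} m")
```

prints

```
design range: [0.253, 0.273] m
recommended step depth: [0.259, 0.273] m, prefer 0.273 m
```

The first line is today's safe window: treads shallower than 0.253 m let
the fastest plausible walker's XCoM pass the tread edge on a 12-step
flight; deeper than 0.273 m and the step-by-step stride no longer
reaches. The second line future-proofs the lower bound for the cohort of
30 years hence (taller children drift further per step) while keeping
the upper bound constrained by today's occupants, and prefers the larger
value to absorb behavioural deviations. The corresponding published
totals are (0.250, 0.282) with final recommendation (0.258, 0.282);
residuals are reported in `dr.provenance`, since the published totals
are not exactly reconstructible from their printed inputs (see
`docs/methods.md`).

The `examples/` directory walks each capability: synthetic cohort
generation, gait summaries, staircase audits, the design-range
combination, growth projection and the full pipeline. A quick audit from
the shell:

```sh
$ stairsafe audit-staircase -d 0.28
  ...
  overall safe window: [0.248, 0.303] m
  verdict: SAFE
```

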