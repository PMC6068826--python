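"""Audit a staircase with the inverted-pendulum stability model.

At the study's sample-mean parameters the per-step drift of the
extrapolated CoM is v*sqrt(l/g) ~ 0.253 m.  A flight is safe when its
depth lies between the closed-form minimum (the critical CoP must stay
on the Nth tread) and maximum (the step-by-step stride must still reach)
for every flight length N in 7..12.
"""

from stairsafe import ModelParams, audit_staircase, delta_com, simulate_descent
from stairsafe.stability import StaircaseSpec, study_sites

params = ModelParams(v=0.88, l=0.81, L=0.224, eta=0.11, pfc=0.08)
print(f"per-step XCoM drift: {delta_com(params.v, params.l):.3f} m\n")

audit = audit_staircase(study_sites()["chengguan"], params)
print(audit.render_text())

print()
shallow = StaircaseSpec(name="shallow", riser_height=0.15, step_depth=0.20,
                        step_width=1.4, n_steps=12)
audit2 = audit_staircase(shallow, params)
print(audit2.render_text())

print()
states = simulate_descent(params, shallow)
first_bad = next(s for s in states if s.risky)
print(f"step-by-step oracle: on step {first_bad.step_index} the critical CoP "
      f"sits {-first_bad.margin:.3f} m past the tread edge (negative margin "
      "of stability = fall risk).")
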