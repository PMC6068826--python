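"""Project the design range over a 30-year service life.

Children's mean height grows ~0.44 cm/yr and foot length ~0.16 cm/yr;
the pendulum length follows height through the within-sample regression
l = (0.3484*height_cm + 33.518)/100.  Taller future cohorts need deeper
treads, so the recommendation pairs the projected lower bound with the
present upper bound and prefers the larger value in between.
"""

from stairsafe import project_design_range, reference_parameter_table

table = reference_parameter_table()
result = project_design_range(table, horizon=30)

for t in result.decades:
    dr = result.ranges[t]
    print(f"  +{t:>4.0f} y: design range [{dr.d_low:.3f}, {dr.d_high:.3f}] m")

rec = result.recommended
print()
print(f"lower-bound drift: {result.drift_per_decade*1000:.1f} mm per decade")
print(f"recommended step depth: [{rec.low:.3f}, {rec.high:.3f}] m, "
      f"prefer {rec.preferred:.3f} m")
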