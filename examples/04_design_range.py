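"""Derive the step-depth design range from parameter uncertainty.

Each parameter (PFC, eta, v, l) sweeps its 95% t-interval with the
others at sample means, and the flight length N sweeps 7..12; the design
window is [max of the lower-bound values, min of the upper-bound
values].  Residuals against the published totals (0.250, 0.282) are
reported, since those totals are not exactly reconstructible from the
printed inputs.
"""

from stairsafe import combine_subranges, reference_parameter_table

table = reference_parameter_table()
for name, est in table.items():
    if est.fixed_range:
        print(f"  {name:>3}: N in {est.fixed_range}")
    else:
        print(f"  {name:>3}: {est.mean} +/- {est.sd}  ->  "
              f"CI ({est.ci_low:.3f}, {est.ci_high:.3f})")

dr = combine_subranges(table)
print()
for p, sub in dr.subranges.items():
    print(f"  {p:>3}: lower bound in {tuple(round(x,3) for x in sub['lower'])}, "
          f"upper bound in {tuple(round(x,3) for x in sub['upper'])}")
print()
print(f"design range: [{dr.d_low:.3f}, {dr.d_high:.3f}] m")
print(f"residuals vs published (0.250, 0.282): "
      f"{dr.provenance['residual_low']:+.4f} / {dr.provenance['residual_high']:+.4f}")
print(f"binding lower case: {dr.provenance['binding_lower']}")
print()
print("The lower bound binds at the fastest plausible walker on the longest")
print("flight; treads shallower than it put the extrapolated CoM past the edge.")
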