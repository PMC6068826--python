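"""Generate a synthetic 72-student cohort and inspect its anthropometrics.

Draws 12 students per grade (grades 1-6) from the grade-stratified
truncated-normal distributions that emulate the field study's sample,
then prints the per-grade means of the quantities the stability model
uses: pendulum length l (CoM to ankle), foot length L, and the
heel-to-critical-CoP distance eta.
"""

from stairsafe import CohortConfig, generate_cohort

cfg = CohortConfig(seed=1)
cohort = generate_cohort(cfg)

print(f"cohort of {len(cohort)} students (seed {cfg.seed})")
print(cohort.groupby("grade")[["height_cm", "l_m", "foot_length_m", "eta_m"]]
      .mean().round(3))
print()
print("Each row is a grade's sample mean; l grows with height (the taller")
print("the student, the longer the pendulum and the larger the per-step")
print("drift of the extrapolated centre of mass).")
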