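"""Reference values from the published field study that this package reanalyses.

The study measured 72 primary-school students (grades 1-6, 12 per grade)
descending three school staircases under three scenarios (alone, in pairs,
evacuation), and derived a stampede-prevention design range for step depth.
Everything here is a printed input: staircase geometry, grade-stratified
anthropometrics, the selected model parameters with their published
confidence intervals and per-parameter design subranges, and the linear
growth trends used for service-life projection.

These constants serve two purposes: they are the defaults of the synthetic
cohort generator, and they are the comparison targets of the report writers
(``render_table5`` prints "published vs computed" columns from them).

Units follow the field convention: lengths in metres unless a ``_cm``
suffix says otherwise, speeds in m/s, angles in degrees.
"""

from __future__ import annotations

#: Number of subjects in the study sample (12 per grade, grades 1-6).
N_SUBJECTS = 72

#: Consecutive-step counts over which the design range is combined.
STEP_RANGE = (7, 12)

#: Two-sided confidence level used throughout (alpha = 0.05).
ALPHA = 0.05

# ---------------------------------------------------------------------------
# Staircase geometry of the three experiment sites (riser height h, step
# depth d, step width w in metres; published inclination in degrees;
# steps per flight). Subjects 1-24, 25-48 and 49-72 used the three sites
# respectively.
SITE_GEOMETRY = {
    "gugua": dict(riser_height=0.15, step_depth=0.30, step_width=1.60,
                  incline_deg=26.57, n_steps=12, subjects=(1, 24)),
    "zhongle": dict(riser_height=0.15, step_depth=0.29, step_width=1.45,
                    incline_deg=27.35, n_steps=12, subjects=(25, 48)),
    "chengguan": dict(riser_height=0.15, step_depth=0.28, step_width=1.36,
                      incline_deg=28.18, n_steps=12, subjects=(49, 72)),
}

# ---------------------------------------------------------------------------
# Grade-stratified anthropometrics (mean, SD) of the single-support phase.
# Heights are stored in cm: the published table prints them on an
# implausible decimal scale ("0.121 +/- 5.3" m); the means are read as
# x10 cm (121-151 cm, consistent with the l-height regression in cm) and
# the sub-unit SDs as cm x100. The grade-5 foot-length SD is printed as
# 0.17 m (~75% of the mean); 0.017 m is shipped instead.
GRADE_ANTHROPOMETRICS = {
    1: dict(age_yr=(8.0, 0.0), shoulder_width_m=(0.286, 0.02),
            height_cm=(121.0, 5.3), l_m=(0.750, 0.03), foot_length_m=(0.216, 0.02)),
    2: dict(age_yr=(9.0, 0.0), shoulder_width_m=(0.296, 0.01),
            height_cm=(127.0, 3.0), l_m=(0.778, 0.03), foot_length_m=(0.215, 0.02)),
    3: dict(age_yr=(10.1, 0.3), shoulder_width_m=(0.305, 0.01),
            height_cm=(132.0, 4.0), l_m=(0.795, 0.05), foot_length_m=(0.225, 0.02)),
    4: dict(age_yr=(11.1, 0.7), shoulder_width_m=(0.315, 0.01),
            height_cm=(140.0, 5.0), l_m=(0.815, 0.03), foot_length_m=(0.224, 0.01)),
    5: dict(age_yr=(11.3, 0.8), shoulder_width_m=(0.324, 0.02),
            height_cm=(148.0, 7.0), l_m=(0.855, 0.02), foot_length_m=(0.229, 0.017)),
    6: dict(age_yr=(12.1, 0.3), shoulder_width_m=(0.356, 0.02),
            height_cm=(151.0, 8.0), l_m=(0.865, 0.02), foot_length_m=(0.238, 0.01)),
}

#: Heel-to-CoP-junction distance eta (mean, SD) in metres. The critical
#: forward CoP position sits at the midfoot/forefoot junction, eta from
#: the heel and L - eta from the toes.
ETA_M = (0.11, 0.01)

# ---------------------------------------------------------------------------
# Scenario-dependent horizontal descent speeds (mean, SD) in m/s.
# Alone and evacuation are published sample-wide values; the paired value
# pools the three published site values (0.83/0.76/0.86).
SCENARIO_SPEEDS = {
    "alone": (0.91, 0.13),
    "paired": (0.82, 0.10),
    "evacuation": (0.88, 0.08),
}

#: Posterior foot clearance (heel to riser), paired-scenario sample value
#: selected as the model reference.
PFC_M = (0.084, 0.02)

#: Anterior foot clearance (toes past the tread edge, negative = overhang),
#: alone-scenario sample value. The model fixes the initial AFC at 0.
AFC_M = (-0.02, 0.02)

# ---------------------------------------------------------------------------
# Model parameters as selected by the study for the design-range table
# (mean, SD), sample size N_SUBJECTS, plus the published interval
# estimates and per-parameter step-depth subranges for comparison.
SAMPLE_MEANS = {
    "pfc": (0.08, 0.02),
    "eta": (0.11, 0.01),
    "v": (0.88, 0.08),
    "l": (0.81, 0.09),
    "L": (0.224, 0.02),
}

#: Published design-range table rows: interval estimate, then the (min,
#: max) of the step-depth lower bound and upper bound as the row's
#: parameter sweeps its interval. The v interval (0.711, 0.745) is
#: inconsistent with the t-formula applied to 0.88 +/- 0.08, n = 72
#: (which gives (0.861, 0.899)); it is kept verbatim for comparison.
PUBLISHED_SUBRANGES = {
    "pfc": dict(ci=(0.075, 0.085), lower=(0.242, 0.245), upper=(0.296, 0.330)),
    "eta": dict(ci=(0.108, 0.112), lower=(0.245, 0.246), upper=(0.295, 0.297)),
    "v": dict(ci=(0.711, 0.745), lower=(0.241, 0.250), upper=(0.291, 0.302)),
    "l": dict(ci=(0.789, 0.831), lower=(0.242, 0.248), upper=(0.293, 0.300)),
    "N": dict(ci=(7, 12), lower=(0.242, 0.245), upper=(0.296, 0.329)),
}

#: Published combined design range (max of lower subranges, min of upper).
PUBLISHED_DESIGN_RANGE = (0.250, 0.282)

#: Published 30-year growth-adjusted forecast of the design range.
PUBLISHED_PROJECTED_RANGE = (0.258, 0.294)

#: Published final recommendation: future-proofed lower bound, present
#: upper bound. The larger value in the interval is preferred.
PUBLISHED_RECOMMENDATION = (0.258, 0.282)

# ---------------------------------------------------------------------------
# Linear growth trends for 7-12 year olds (cm per year of calendar time)
# fitted by the study to national records, and the within-sample
# regression of pendulum length on height (both in cm).
HEIGHT_TREND = dict(slope=0.4359, intercept=78.033, r_squared=0.98)
FOOT_LENGTH_TREND = dict(slope=0.1629, intercept=18.208, r_squared=0.97)

#: l = (0.3484 * height_cm + 33.518) / 100 metres, R^2 = 0.73.
L_HEIGHT_REGRESSION = dict(slope=0.3484, intercept=33.518, r_squared=0.73)
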