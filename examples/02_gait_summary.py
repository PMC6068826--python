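"""Simulate descent trials and summarise gait per scenario.

Each subject descends one staircase twice per scenario; the speed is the
pause-corrected v = N*d / (T - Tp).  Alone > paired > (evacuation sits
between) is the expected ordering of mean speeds.
"""

from stairsafe import CohortConfig, generate_cohort, generate_trials, summarize
from stairsafe.gait import select_reference_parameters
from stairsafe.stability import study_sites

cfg = CohortConfig(seed=1)
cohort = generate_cohort(cfg)
site = study_sites()["chengguan"]

trials = []
for scenario in ("alone", "paired", "evacuation"):
    trials += generate_trials(cohort, site, scenario, cfg)

summaries = summarize(trials, site.step_depth, by=("scenario",))
print(summaries.round(3).to_string(index=False))

refs = select_reference_parameters(summaries, "table5")
print()
print(f"reference speed (evacuation): {refs['v'].mean} +/- {refs['v'].sd} m/s")
print(f"reference PFC (paired):       {refs['pfc'].mean} +/- {refs['pfc'].sd} m")
print()
print("The evacuation speed and paired-scenario posterior foot clearance,")
print("rounded to table precision, feed the step-depth design range.")
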