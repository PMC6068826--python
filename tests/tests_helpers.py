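"""Shared helpers for the test suite."""

from stairsafe import CohortConfig, PipelineConfig
from stairsafe.cohort import Normal


def zero_variance_cohort_config(seed: int = 0) -> CohortConfig:
    """All SDs zero: every draw collapses to the configured means."""
    cfg = CohortConfig(seed=seed)
    grades = {
        g: p.model_copy(update={
            k: Normal(mean=getattr(p, k).mean, sd=0.0)
            for k in ("age_yr", "height_cm", "shoulder_width_m", "l_m",
                      "foot_length_m")
        })
        for g, p in cfg.anthropometrics.items()
    }
    # a single grade: between-grade spread would otherwise keep the pooled
    # cohort SDs nonzero even with zero within-grade variance
    return cfg.model_copy(update={
        "grades": (4,),
        "anthropometrics": grades,
        "eta_m": Normal(mean=cfg.eta_m.mean, sd=0.0),
        "pfc_m": Normal(mean=cfg.pfc_m.mean, sd=0.0),
        "afc_m": Normal(mean=cfg.afc_m.mean, sd=0.0),
        "scenario_speeds": {k: Normal(mean=v.mean, sd=0.0)
                            for k, v in cfg.scenario_speeds.items()},
        "pause_prob": 0.0,
    })


def zero_variance_pipeline_config(seed: int = 0) -> PipelineConfig:
    return PipelineConfig(seed=seed, cohort=zero_variance_cohort_config(seed))
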