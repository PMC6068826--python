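"""Synthetic cohort generator: determinism, distributions, trial structure."""

import numpy as np
import pandas as pd
import pytest

from stairsafe import CohortConfig, descent_speed, generate_cohort, generate_trials
from stairsafe.cohort import Normal, frame_to_trials, trials_to_frame
from stairsafe.stability import StaircaseSpec, study_sites


@pytest.fixture(scope="module")
def default_cohort():
    return generate_cohort(CohortConfig(seed=42))


def zero_sd_config(**kw):
    cfg = CohortConfig(seed=0, **kw)
    grades = {
        g: p.model_copy(update={
            k: Normal(mean=getattr(p, k).mean, sd=0.0)
            for k in ("age_yr", "height_cm", "shoulder_width_m", "l_m", "foot_length_m")
        })
        for g, p in cfg.anthropometrics.items()
    }
    return cfg.model_copy(update={
        "anthropometrics": grades,
        "eta_m": Normal(mean=cfg.eta_m.mean, sd=0.0),
    })


class TestGenerateCohort:
    def test_study_sized_cohort(self, default_cohort):
        assert len(default_cohort) == 72
        assert default_cohort.groupby("grade").size().eq(12).all()
        assert list(default_cohort["subject_id"]) == list(range(1, 73))

    def test_lengths_positive_and_eta_inside_foot(self, default_cohort):
        for col in ("height_cm", "l_m", "foot_length_m", "eta_m"):
            assert (default_cohort[col] > 0).all()
        assert (default_cohort["eta_m"] < default_cohort["foot_length_m"]).all()

    def test_per_grade_mean_within_three_se(self, default_cohort):
        cfg = CohortConfig()
        for grade, grp in default_cohort.groupby("grade"):
            p = cfg.anthropometrics[grade].l_m
            se = p.sd / np.sqrt(len(grp))
            assert abs(grp["l_m"].mean() - p.mean) < 3 * se

    def test_zero_sd_collapses_to_means(self):
        cohort = generate_cohort(zero_sd_config())
        for grade, grp in cohort.groupby("grade"):
            p = CohortConfig().anthropometrics[grade]
            assert (grp["l_m"] == p.l_m.mean).all()
            assert (grp["height_cm"] == p.height_cm.mean).all()

    def test_same_seed_byte_identical_csv(self, tmp_path):
        paths = []
        for i in (1, 2):
            p = tmp_path / f"c{i}.csv"
            generate_cohort(CohortConfig(seed=99)).to_csv(p, index=False)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_different_seeds_differ(self):
        a = generate_cohort(CohortConfig(seed=1))
        b = generate_cohort(CohortConfig(seed=2))
        assert not a.equals(b)

    def test_invalid_configs_rejected(self):
        with pytest.raises(Exception):
            CohortConfig(n_per_grade=0)
        with pytest.raises(Exception):
            CohortConfig(grades=())
        with pytest.raises(Exception):
            CohortConfig(pause_prob=1.5)

    def test_distributional_fidelity_at_large_n(self):
        """With n = 10,000 draws, sample mean and SD track the configured
        values to within 2%."""
        cfg = CohortConfig(n_per_grade=10_000, grades=(4,), seed=3)
        cohort = generate_cohort(cfg)
        p = cfg.anthropometrics[4]
        for col, dist in (("height_cm", p.height_cm), ("l_m", p.l_m),
                          ("foot_length_m", p.foot_length_m)):
            assert cohort[col].mean() == pytest.approx(dist.mean, rel=0.02)
            assert cohort[col].std(ddof=1) == pytest.approx(dist.sd, rel=0.02)


class TestGenerateTrials:
    def test_trial_count_and_sites(self, default_cohort):
        cfg = CohortConfig(trials_per_subject=2)
        site = study_sites()["chengguan"]
        trials = generate_trials(default_cohort, site, "evacuation", cfg)
        assert len(trials) == 2 * len(default_cohort)
        assert all(t.site == "chengguan" and t.n_steps == 12 for t in trials)

    def test_pause_free_speed_round_trip(self, default_cohort):
        """With no pauses the speed formula recovers the drawn speed exactly."""
        cfg = CohortConfig(pause_prob=0.0)
        site = study_sites()["gugua"]
        for t in generate_trials(default_cohort, site, "evacuation", cfg):
            assert descent_speed(t, site.step_depth) == pytest.approx(
                t.v_drawn, rel=1e-9)

    def test_alone_and_paired_have_no_pauses(self, default_cohort):
        cfg = CohortConfig(pause_prob=0.9)
        site = study_sites()["gugua"]
        for scenario in ("alone", "paired"):
            assert all(t.Tp == 0.0 for t in
                       generate_trials(default_cohort, site, scenario, cfg))

    def test_certain_pauses_add_exactly_n_times_duration(self, default_cohort):
        cfg = CohortConfig(pause_prob=1.0,
                           pause_duration_s=Normal(mean=1.25, sd=0.0))
        site = study_sites()["zhongle"]
        n = site.n_steps
        for t in generate_trials(default_cohort.head(5), site, "evacuation", cfg):
            no_pause_time = n * site.step_depth / t.v_drawn
            assert t.T - no_pause_time == pytest.approx(n * 1.25, rel=1e-9)
            assert t.Tp == pytest.approx(n * 1.25, rel=1e-9)

    def test_unknown_scenario_rejected(self, default_cohort):
        with pytest.raises(ValueError, match="scenario"):
            generate_trials(default_cohort, study_sites()["gugua"], "jogging",
                            CohortConfig())

    def test_speed_recovery_within_three_se(self, default_cohort):
        """Evacuation speeds regenerate the configured 0.88 +/- 0.08 m/s."""
        cfg = CohortConfig(seed=11)
        site = study_sites()["chengguan"]
        trials = generate_trials(default_cohort, site, "evacuation", cfg)
        speeds = np.array([descent_speed(t, site.step_depth) for t in trials])
        se = 0.08 / np.sqrt(len(speeds))
        assert abs(speeds.mean() - 0.88) < 3 * se

    def test_deterministic_per_seed_and_stream_independent_of_scenario_order(
            self, default_cohort):
        cfg = CohortConfig(seed=5)
        site = study_sites()["gugua"]
        a = generate_trials(default_cohort, site, "paired", cfg)
        generate_trials(default_cohort, site, "alone", cfg)  # interleaved call
        b = generate_trials(default_cohort, site, "paired", cfg)
        assert a == b


class TestTrialFrames:
    def test_round_trip_through_long_frame(self, default_cohort):
        cfg = CohortConfig(seed=2)
        site = study_sites()["chengguan"]
        trials = generate_trials(default_cohort.head(6), site, "evacuation", cfg)
        df = trials_to_frame(trials)
        assert set(df.columns) >= {"subject_id", "scenario", "site", "step_index",
                                   "crossing_time_s", "pfc_m", "afc_m"}
        back = frame_to_trials(df)
        key = lambda t: (t.subject_id, t.trial)
        for orig, rt in zip(sorted(trials, key=key), sorted(back, key=key)):
            assert rt.events == orig.events
            assert rt.Tp == pytest.approx(orig.Tp)
            assert rt.pfc == orig.pfc and rt.afc == orig.afc

    def test_csv_round_trip_preserves_speeds(self, tmp_path, default_cohort):
        cfg = CohortConfig(seed=2, pause_prob=0.0)
        site = study_sites()["gugua"]
        trials = generate_trials(default_cohort.head(4), site, "evacuation", cfg)
        path = tmp_path / "trials.csv"
        trials_to_frame(trials).to_csv(path, index=False)
        back = frame_to_trials(pd.read_csv(path))
        for orig, rt in zip(sorted(trials, key=lambda t: (t.subject_id, t.trial)),
                            sorted(back, key=lambda t: (t.subject_id, t.trial))):
            assert descent_speed(rt, site.step_depth) == pytest.approx(
                descent_speed(orig, site.step_depth), rel=1e-12)
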