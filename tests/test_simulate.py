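"""Virtual cohort generator: scan schedule, per-mouse trajectories,
cohort-level determinism and the qualitative dose/strain orderings."""

import dataclasses

import numpy as np
import pytest

from braintox import (
    C3H_HE,
    SimulationConfig,
    StrainSpec,
    build_schedule,
    default_config,
    fit_volume_model,
    predict_volume,
    simulate_cohort,
    simulate_mouse,
    time_to_volume,
)


def cfg_with(**kwargs) -> SimulationConfig:
    return dataclasses.replace(default_config(), **kwargs)


def rng():
    return np.random.default_rng(0)


class TestSchedule:
    def test_default_grid_with_first_scan_week_one(self):
        cfg = cfg_with(first_scan_choices=(1,))
        assert build_schedule(cfg, rng()) == [-1, 1, 3, 5, 7, 9, 11, 13, 18, 23, 26]

    def test_first_scan_week_two(self):
        cfg = cfg_with(first_scan_choices=(2,))
        weeks = build_schedule(cfg, rng())
        assert weeks[:2] == [-1, 2]
        assert weeks[-1] == 26

    def test_short_followup(self):
        cfg = cfg_with(first_scan_choices=(1,), max_followup=3.0, late_start=2.0)
        assert build_schedule(cfg, rng()) == [-1, 1, 3]

    def test_terminal_cap_only_when_grid_overshoots(self):
        cfg = cfg_with(first_scan_choices=(1,), max_followup=23.0)
        assert build_schedule(cfg, rng())[-2:] == [18, 23]


class TestSimulateMouse:
    def test_control_mouse_is_blank_and_censored(self):
        cfg = cfg_with(sigma_log10=0.0)
        tr = simulate_mouse("ctl", "C3H/He", 0.0, C3H_HE, cfg, rng())
        assert all(v == 0.0 for v in tr.volumes)
        assert tr.observed_onset is None
        assert tr.event == 0 and tr.last_week == 26.0

    def test_subthreshold_dose_develops_no_lesion(self):
        cfg = cfg_with(sigma_log10=0.0)
        tr = simulate_mouse("lo", "C3H/He", 25.0, C3H_HE, cfg, rng())
        assert all(v == 0.0 for v in tr.volumes)

    def test_noise_free_volumes_follow_growth_law(self):
        cfg = cfg_with(sigma_log10=0.0, first_scan_choices=(1,),
                       sacrifice_threshold=1e6, brain_volume_cap=1e9)
        tr = simulate_mouse("hi", "C3H/He", 80.0, C3H_HE, cfg, rng())
        assert tr.observed_onset == 1.0  # latent onset 0.975 -> first scan
        for w, v in zip(tr.scan_weeks, tr.volumes):
            if w >= 1.0:
                assert v == pytest.approx(predict_volume(80.0, w, C3H_HE), rel=1e-12)
            else:
                assert v == 0.0

    def test_pre_onset_scans_read_zero(self):
        cfg = cfg_with(sigma_log10=0.0, first_scan_choices=(1,))
        tr = simulate_mouse("mid", "C3H/He", 60.0, C3H_HE, cfg, rng())
        # latent onset at 60 Gy is 4.571 weeks -> detected at the week-5 scan
        assert tr.observed_onset == 5.0
        assert all(v == 0.0 for w, v in zip(tr.scan_weeks, tr.volumes) if w < 5.0)

    def test_sacrifice_at_first_scan_reaching_threshold(self):
        cfg = cfg_with(sigma_log10=0.0, first_scan_choices=(1,), sacrifice_threshold=60.0)
        crossing = time_to_volume(60.0, 80.0, C3H_HE)
        assert crossing == pytest.approx(7.9738, abs=1e-3)
        tr = simulate_mouse("hi", "C3H/He", 80.0, C3H_HE, cfg, rng())
        assert tr.event == 1
        assert tr.last_week == 9.0  # first scheduled scan at or after 7.97 weeks
        assert tr.scan_weeks[-1] == 9.0 and tr.volumes[-1] >= 60.0

    def test_brain_volume_cap_clips_with_warning(self):
        # without sacrifice, the 80 Gy growth law exceeds the whole-brain
        # volume near the end of follow-up and must be clipped
        cfg = cfg_with(sigma_log10=0.0, first_scan_choices=(1,),
                       sacrifice_threshold=1e6, detection_threshold=0.5)
        with pytest.warns(RuntimeWarning, match="clipped"):
            tr = simulate_mouse("hi", "C3H/He", 80.0, C3H_HE, cfg, rng())
        assert max(tr.volumes) == cfg.brain_volume_cap


class TestSimulateCohort:
    def test_default_layout_has_twenty_mice(self, noisy_cohort):
        assert len(noisy_cohort) == 20
        for strain in ("C3H/He", "C57BL/6"):
            assert len(noisy_cohort.for_strain(strain)) == 10

    def test_same_seed_reproduces_identical_tables(self):
        a = simulate_cohort(default_config(seed=7))
        b = simulate_cohort(default_config(seed=7))
        assert a.scan_frame().equals(b.scan_frame())
        assert a.survival_frame().equals(b.survival_frame())

    def test_different_seed_changes_volumes(self):
        a = simulate_cohort(default_config(seed=7))
        b = simulate_cohort(default_config(seed=8))
        assert not a.scan_frame().equals(b.scan_frame())

    def test_existing_mice_stable_under_cohort_growth(self):
        # per-mouse random sub-streams: adding animals must not reshuffle
        # the trajectories of the mice already present
        small = simulate_cohort(default_config(seed=3))
        spec = default_config().strain_specs[0]
        big_cfg = cfg_with(seed=3, strain_specs=(
            dataclasses.replace(spec, n_per_dose=5),
        ))
        big = simulate_cohort(big_cfg)
        for tr in small.for_strain(spec.strain_label):
            twin = next(t for t in big if t.mouse_id == tr.mouse_id)
            assert twin.scan_weeks == tr.scan_weeks
            assert twin.volumes == tr.volumes

    def test_noise_free_extreme_dose_outcomes(self, noise_free_cohort):
        for tr in noise_free_cohort:
            if tr.dose in (40.0, 45.0, 0.0):
                assert tr.event == 0 and tr.last_week == 26.0
            if tr.dose in (80.0, 85.0):
                assert tr.event == 1 and tr.last_week < 26.0

    def test_mean_onset_is_dose_ordered_within_strain(self):
        for seed in range(5):
            table = simulate_cohort(default_config(seed=seed))
            for strain in table.strains:
                obs = table.for_strain(strain).onset_observations()
                by_dose = {}
                for o in obs:
                    by_dose.setdefault(o.dose, []).append(o.onset_week)
                doses = sorted(by_dose)
                means = [np.mean(by_dose[d]) for d in doses]
                assert all(m1 >= m2 for m1, m2 in zip(means, means[1:]))

    def test_sensitive_strain_reaches_sacrifice_first(self):
        # growth exponent 0.40 vs 0.28: the sensitive strain's highest dose
        # group leaves the experiment earlier than the resistant strain's
        for seed in range(5):
            table = simulate_cohort(default_config(seed=seed))
            high = {
                "C3H/He": [t.last_week for t in table if t.dose == 80.0],
                "C57BL/6": [t.last_week for t in table if t.dose == 85.0],
            }
            assert np.mean(high["C3H/He"]) < np.mean(high["C57BL/6"])

    def test_noise_free_closure_recovers_generator(self, noise_free_cohort):
        pts = noise_free_cohort.for_strain("C3H/He").volume_points()
        fit = fit_volume_model(pts)
        assert fit.params.a == pytest.approx(0.0155, rel=1e-3)
        assert fit.params.b == pytest.approx(0.40, rel=1e-3)
        assert fit.params.d0 == pytest.approx(30.0, rel=1e-3)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"max_followup": 10.0, "late_start": 13.0},
            {"detection_threshold": 0.0},
            {"sacrifice_threshold": 0.5},  # below detection threshold
            {"sigma_log10": -0.1},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            cfg_with(**kwargs)

    def test_json_round_trip(self):
        cfg = default_config(seed=11)
        assert SimulationConfig.from_json(cfg.to_json()) == cfg
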