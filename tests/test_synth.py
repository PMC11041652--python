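"""Generators: planted structure, determinism, and closed-form checks."""

import numpy as np
import pytest
from scipy import stats

import lhbpipe as lp
from lhbpipe.behavior import session_summary
from lhbpipe.imaging import compute_dff


class TestTaskSchedule:
    def test_habituation_counts(self, schedules):
        hab, _ = schedules
        counts = hab.cue_counts()
        assert counts[lp.Cue.CS_PLUS] == 30
        assert counts[lp.Cue.CS_MINUS] == 30
        assert counts[lp.Cue.US_UNPREDICTED] == 5
        assert not any(t.paired_us for t in hab.trials)

    def test_conditioning_counts_and_pairing(self, schedules):
        _, cond = schedules
        counts = cond.cue_counts()
        assert counts[lp.Cue.CS_PLUS] == 30
        assert counts[lp.Cue.CS_MINUS] == 30
        assert counts[lp.Cue.US_UNPREDICTED] == 0
        assert all(
            t.paired_us == (t.cue is lp.Cue.CS_PLUS) for t in cond.trials
        )

    def test_iti_bounds(self, schedules):
        for sched in schedules:
            gaps = np.diff([t.onset_s for t in sched.trials])
            assert gaps.min() >= 30.0 and gaps.max() <= 45.0

    def test_determinism(self):
        a = lp.generate_task_schedule(lp.Phase.CONDITIONING, 5)
        b = lp.generate_task_schedule(lp.Phase.CONDITIONING, 5)
        assert a.trials == b.trials


class TestSpikeCohort:
    def test_determinism(self):
        p = lp.SpikeCohortParams(n_neurons=3, seed=9, duration_s=60.0)
        a, _ = lp.generate_spike_cohort(p)
        b, _ = lp.generate_spike_cohort(p)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.spike_times_s, rb.spike_times_s)

    def test_null_cohort_has_unit_ratios(self):
        p = lp.SpikeCohortParams(n_neurons=20, effect_ratio=1.0,
                                 duration_s=30.0, seed=1)
        _, truth = lp.generate_spike_cohort(p)
        assert (truth["effect_ratio"] == 1.0).all()
        assert (truth["true_modulation"] == 0.0).all()

    def test_poisson_burst_index_matches_closed_form(self):
        """Exponential ISIs at rate r: P(ISI < 25 ms) = 1 - exp(-0.025 r)."""
        rate = 5.0
        p = lp.SpikeCohortParams(
            n_neurons=4, baseline_rate_median_hz=rate, baseline_rate_sigma=0.0,
            burst_prob=0.0, isi_shape_range=(1.0, 1.0), effect_ratio=1.0,
            duration_s=600.0, n_fs_trials=1, seed=2,
        )
        recs, _ = lp.generate_spike_cohort(p)
        expected = 1.0 - np.exp(-0.025 * rate)
        measured = np.mean(
            [lp.spike_train_features(r).burst_index for r in recs]
        )
        assert measured == pytest.approx(expected, abs=0.02)

    def test_planted_coupling_matches_copula_prediction(self):
        """Realized corr(log rate, modulation) equals rho attenuated by the
        three-level class discretization (analytic normal-copula oracle)."""
        rho = -0.5
        p = lp.SpikeCohortParams(n_neurons=200, coupling_rho=rho, seed=3,
                                 duration_s=30.0)
        _, truth = lp.generate_spike_cohort(p)
        r = np.corrcoef(np.log(truth["baseline_rate_hz"]),
                        truth["true_modulation"])[0, 1]
        fe, fi = p.frac_excited, p.frac_inhibited
        e_zv = stats.norm.pdf(stats.norm.ppf(1 - fe)) + stats.norm.pdf(
            stats.norm.ppf(fi))
        sd_v = np.sqrt((fe + fi) - (fe - fi) ** 2)
        expected = rho * e_zv / sd_v
        assert r < 0
        assert r == pytest.approx(expected, abs=0.15)

    def test_infeasible_coupling_rejected(self):
        with pytest.raises(ValueError, match="coupling_rho"):
            lp.SpikeCohortParams(coupling_rho=-1.5)
        with pytest.raises(ValueError, match="coupling_rho"):
            lp.SpikeCohortParams(coupling_rho=0.3)


class TestCalciumCohort:
    def test_noiseless_peak_equals_amplitude(self, schedules):
        hab, cond = schedules
        p = lp.CalciumCohortParams(
            n_neurons=2, prob_excited=1.0, prob_inhibited=0.0,
            prob_nonresponsive=0.0, response_amp_cond=20.0, noise_sd=0.0,
            trial_gain_sd=0.0, seed=4,
        )
        pairs, truth = lp.generate_calcium_cohort(p, hab, cond)
        assert (truth["neurons"]["klass"] == "excited").all()
        ts = compute_dff(pairs[0][1])
        cs_plus = ts.dff_pct[ts.trial_mask(lp.Cue.CS_PLUS)]
        # cue response peaks at exactly the planted amplitude
        w = ts.window
        cue_window = cs_plus[:, w.sample_slice(0.0, 1.4)]
        assert cue_window.max(axis=1) == pytest.approx(20.0, abs=1e-9)
        cs_minus = ts.dff_pct[ts.trial_mask(lp.Cue.CS_MINUS)]
        assert np.abs(cs_minus).max() < 1e-9

    def test_us_response_shares_sign(self, schedules):
        hab, cond = schedules
        p = lp.CalciumCohortParams(
            n_neurons=1, prob_excited=0.0, prob_inhibited=1.0,
            prob_nonresponsive=0.0, noise_sd=0.0, trial_gain_sd=0.0, seed=4,
        )
        pairs, _ = lp.generate_calcium_cohort(p, hab, cond)
        ts = compute_dff(pairs[0][1])
        w = ts.window
        us = ts.dff_pct[ts.trial_mask(lp.Cue.CS_PLUS)][:, w.sample_slice(1.6, 2.6)]
        assert us.min() < -10  # inhibited neuron also dips during the airpuff

    def test_determinism(self, schedules):
        hab, cond = schedules
        p = lp.CalciumCohortParams(n_neurons=2, seed=6)
        a, _ = lp.generate_calcium_cohort(p, hab, cond)
        b, _ = lp.generate_calcium_cohort(p, hab, cond)
        assert np.array_equal(a[0][1].raw_f, b[0][1].raw_f)


class TestBehaviorGenerator:
    def test_nonlearner_scores_zero(self, schedules):
        hab, cond = schedules
        mice = lp.generate_behavior(
            lp.BehaviorParams(n_mice=2, learner=False, blink_noise_sd=0.0,
                              seed=7),
            hab, cond,
        )
        for h, c in mice:
            assert session_summary(h).discrimination_score == pytest.approx(0.0)
            assert session_summary(c).discrimination_score == pytest.approx(0.0)

    def test_noiseless_depth_gives_exact_score(self, schedules):
        hab, cond = schedules
        mice = lp.generate_behavior(
            lp.BehaviorParams(n_mice=1, cr_depth_cond=0.3, blink_noise_sd=0.0,
                              cr_depth_hab=0.0, seed=7),
            hab, cond,
        )
        s = session_summary(mice[0][1])
        assert s.cr_mean_csplus == pytest.approx(70.0)
        assert s.cr_mean_csminus == pytest.approx(100.0)
        assert s.discrimination_score == pytest.approx(30.0)

    def test_full_coupling_preserves_rank_order(self, schedules):
        """With coupling 1 and no blink noise, CS+ CR depth is monotone in
        the shared responsive-neuron trial gain."""
        hab, cond = schedules
        p = lp.CalciumCohortParams(n_neurons=5, seed=8)
        _, truth = lp.generate_calcium_cohort(p, hab, cond)
        mice = lp.generate_behavior(
            lp.BehaviorParams(n_mice=1, neuron_coupling=1.0,
                              blink_noise_sd=0.0, seed=8),
            hab, cond, truth,
        )
        s = session_summary(mice[0][1])
        plus = [c is lp.Cue.CS_PLUS for c in s.cue_per_trial]
        cr_plus = s.cr_amplitude_per_trial[plus]
        gains = truth["trial_gain"][lp.Phase.CONDITIONING]
        cs_trials = [t.cue in (lp.Cue.CS_PLUS, lp.Cue.CS_MINUS)
                     for t in cond.trials]
        g_plus = gains[np.array(cs_trials)][plus]
        rho = stats.spearmanr(cr_plus, g_plus).statistic
        assert rho == pytest.approx(-1.0)  # deeper blink = lower CR

    def test_coupling_requires_truth(self, schedules):
        hab, cond = schedules
        with pytest.raises(ValueError, match="ground truth"):
            lp.generate_behavior(
                lp.BehaviorParams(neuron_coupling=0.5), hab, cond
            )


class TestPhotometryGenerator:
    def test_determinism(self, schedules):
        hab, cond = schedules
        p = lp.PhotometryParams(seed=9)
        a = lp.generate_photometry(p, hab, cond)
        b = lp.generate_photometry(p, hab, cond)
        assert np.array_equal(a.counts, b.counts)

    def test_stable_profile_amplitudes(self):
        p = lp.PhotometryParams.for_profile("Glu", "stable", amp=0.4)
        assert p.amp_cs_plus_hab == p.amp_cs_plus_cond == 0.4
        q = lp.PhotometryParams.for_profile("ACh", "potentiating", amp=0.3)
        assert q.amp_cs_plus_cond == pytest.approx(2 * q.amp_cs_plus_hab)

    def test_flat_sensor_fails_validity(self, schedules):
        """With zero transient amplitude the signal-validity rule rejects
        the stationary Poisson recording."""
        hab, cond = schedules
        p = lp.PhotometryParams(
            amp_cs_plus_hab=0.0, amp_cs_minus_hab=0.0, amp_cs_plus_cond=0.0,
            amp_cs_minus_cond=0.0, amp_us=0.0, seed=10,
        )
        series = lp.generate_photometry(p, hab, cond)
        assert not lp.check_signal_validity(series).valid

    def test_responsive_sensor_passes_validity(self, schedules):
        hab, cond = schedules
        series = lp.generate_photometry(lp.PhotometryParams(seed=11), hab, cond)
        assert lp.check_signal_validity(series).valid
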