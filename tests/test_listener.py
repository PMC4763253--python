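import dataclasses

import numpy as np
import pytest

from streamscore import buildup, listener, timeline
from streamscore.listener import (ListenerParams, default_cohort,
                                  simulate_detection_responses,
                                  simulate_percept_trajectory)
from streamscore.timeline import make_trial


def params(**kw):
    return dataclasses.replace(ListenerParams(), **kw)


@pytest.fixture(scope="module")
def attend_trial():
    return make_trial(0, 37, 8, "attend", ("early", "late"), 800.0, seed=1)


@pytest.fixture(scope="module")
def switch_trial():
    return make_trial(1, 37, 8, "switch", ("late",), 800.0, seed=1)


class TestParams:
    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError):
            params(unattended_gain=1.5)
        with pytest.raises(ValueError):
            params(noise_task_acc=-0.1)

    def test_fa_ordering_enforced(self):
        with pytest.raises(ValueError):
            params(fa_rate_int=0.01, fa_rate_seg=0.02)

    def test_cohort_accuracy_within_reported_range(self):
        accs = [p.noise_task_acc for p in default_cohort(12, seed=0)]
        assert all(0.82 <= a <= 0.98 for a in accs)


class TestPerceptTrajectory:
    def test_zero_buildup_rate_stays_integrated(self, attend_trial):
        p = params(buildup_rate_4=0.0, buildup_rate_8=0.0)
        truth, reports = simulate_percept_trajectory(attend_trial, p, seed=0)
        assert all(lab == "one_stream" for lab in truth.latent)
        assert all(lab == "one_stream" for _, lab in reports)

    def test_first_report_always_emitted(self, attend_trial):
        for seed in range(10):
            _, reports = simulate_percept_trajectory(
                attend_trial, ListenerParams(), seed)
            assert len(reports) >= 1

    def test_reports_alternate_and_increase(self, attend_trial):
        for seed in range(20):
            _, reports = simulate_percept_trajectory(
                attend_trial, ListenerParams(), seed)
            times = [t for t, _ in reports]
            labels = [lab for _, lab in reports]
            assert all(t1 < t2 for t1, t2 in zip(times, times[1:]))
            assert all(a != b for a, b in zip(labels, labels[1:]))
            assert all(0 <= t <= attend_trial.duration_s + 1.5 for t in times)

    def test_no_reports_before_switch(self, switch_trial):
        for seed in range(10):
            _, reports = simulate_percept_trajectory(
                switch_trial, ListenerParams(), seed)
            assert all(t >= switch_trial.switch_time_s for t, _ in reports)

    def test_deterministic_from_seed(self, attend_trial):
        a = simulate_percept_trajectory(attend_trial, ListenerParams(), 7)
        b = simulate_percept_trajectory(attend_trial, ListenerParams(), 7)
        assert a[0].latent == b[0].latent
        assert a[1] == b[1]

    def test_buildup_monotone_without_reversals(self):
        """With no segregated-to-integrated hazard the population
        proportion-segregated is nondecreasing in time."""
        p = params(seg_to_int_hazard=0.0)
        trial = make_trial(0, 37, 8, "attend", (), 800.0, seed=1)
        counts = np.zeros(37)
        n = 1500
        for seed in range(n):
            truth, _ = simulate_percept_trajectory(trial, p, seed)
            counts += np.array([lab == "two_streams" for lab in truth.latent])
        prop = counts / n
        assert np.all(np.diff(prop) >= -0.02)

    def test_full_automaticity_matches_attend_statistics(self):
        """rho=1, kappa=1: segregation at matched absolute time is the
        same whether or not attention was on the tones."""
        p = params(unattended_gain=1.0, reset_fraction=1.0)
        att = make_trial(0, 37, 8, "attend", (), 800.0, seed=1)
        swi = make_trial(1, 37, 8, "switch", (), 800.0, seed=1)
        k = 30   # triplet index at 14.5 s, past the switch
        n = 2000
        seg_a = np.mean([simulate_percept_trajectory(att, p, s)[0].latent[k]
                         == "two_streams" for s in range(n)])
        seg_s = np.mean([simulate_percept_trajectory(swi, p, s + n)[0].latent[k]
                         == "two_streams" for s in range(n)])
        se = np.sqrt(seg_a * (1 - seg_a) / n) * 2
        assert abs(seg_a - seg_s) < 3 * max(se, 0.01) + 0.02

    def test_full_reset_matches_attend_realigned(self):
        """rho=0: the post-switch chain restarts, so segregation k windows
        after the switch matches k windows after sequence onset."""
        p = params(unattended_gain=0.0, reset_fraction=0.0)
        att = make_trial(0, 37, 8, "attend", (), 800.0, seed=1)
        swi = make_trial(1, 37, 8, "switch", (), 800.0, seed=1)
        k_post = 10          # 5 s after alignment zero
        k_switch = 25 + k_post
        n = 2000
        seg_a = np.mean([simulate_percept_trajectory(att, p, s)[0].latent[k_post]
                         == "two_streams" for s in range(n)])
        seg_s = np.mean([simulate_percept_trajectory(swi, p, s + n)[0]
                         .latent[k_switch] == "two_streams" for s in range(n)])
        assert abs(seg_a - seg_s) < 0.03


class TestDetectionResponses:
    def test_certain_hits_no_fas_press_every_deviant(self, attend_trial):
        p = params(hit_coefs=(np.inf, 0.0, 0.0, 0.0),
                   fa_rate_int=0.0, fa_rate_seg=0.0)
        sil = sorted(attend_trial.deviant_silence_onsets().values())
        for seed in range(5):
            truth, _ = simulate_percept_trajectory(attend_trial, p, seed)
            presses = simulate_detection_responses(attend_trial, truth, p, seed)
            assert len(presses) == len(sil)
            for press, d in zip(presses, sil):
                assert press > d

    def test_no_presses_before_switch(self, switch_trial):
        p = ListenerParams()
        for seed in range(10):
            truth, _ = simulate_percept_trajectory(switch_trial, p, seed)
            presses = simulate_detection_responses(switch_trial, truth, p, seed)
            assert all(t >= switch_trial.switch_time_s for t in presses)

    def test_false_alarm_poisson_mean(self):
        """Constant 0.01/s false-alarm rate over 18.5-s sequences gives a
        Poisson count with the matching mean."""
        p = params(hit_coefs=(-np.inf, 0, 0, 0), fa_rate_int=0.01,
                   fa_rate_seg=0.01)
        trial = make_trial(0, 37, 8, "attend", (), 800.0, seed=1)
        n_trials = 400
        total = 0
        for seed in range(n_trials):
            truth, _ = simulate_percept_trajectory(trial, p, seed)
            total += len(simulate_detection_responses(trial, truth, p, seed))
        mean = 0.01 * 18.5 * n_trials
        assert abs(total - mean) < 3 * np.sqrt(mean)

    def test_integrated_percept_raises_hit_rate(self):
        """A positive integrated-percept coefficient yields more hits when
        the deviant falls in an integrated phase, at matched conditions."""
        p = params(hit_coefs=(0.5, 0.0, 0.0, 1.5), fa_rate_int=0.0,
                   fa_rate_seg=0.0, buildup_rate_8=0.02)
        trial = make_trial(0, 37, 8, "attend", ("late",), 800.0, seed=1)
        sil = trial.deviant_silence_onsets()["late"]
        k = int(sil // 0.5)
        hits = {True: [0, 0], False: [0, 0]}   # integrated -> [n, hits]
        for seed in range(4000):
            truth, _ = simulate_percept_trajectory(trial, p, seed)
            presses = simulate_detection_responses(trial, truth, p, seed + 1)
            integ = truth.latent[k] == "one_stream"
            hits[integ][0] += 1
            hits[integ][1] += int(any(0 <= t - sil <= 1.5 for t in presses))
        r_int = hits[True][1] / hits[True][0]
        r_seg = hits[False][1] / hits[False][0]
        assert r_int > r_seg + 0.1


class TestSessionSimulation:
    def test_perfect_noise_labelling(self, switch_trial):
        p = params(noise_task_acc=1.0)
        kinds, labels = listener.simulate_noise_labels(switch_trial, p, 3)
        assert len(labels) == len(kinds)
        assert [lab for _, lab in labels] == kinds

    def test_same_seed_identical_logs(self, exp2_design, small_cohort):
        a = listener.simulate_session(exp2_design, small_cohort, seed=9)
        b = listener.simulate_session(exp2_design, small_cohort, seed=9)
        for ra, rb in zip(a.itertuples(), b.itertuples()):
            assert ra.log.percept_reports == rb.log.percept_reports
            assert ra.log.detection_presses == rb.log.detection_presses
            assert ra.log.noise_labels == rb.log.noise_labels

    def test_stage_controls_response_streams(self, small_cohort):
        obj = timeline.make_session("exp1_objective", 3)
        ses = listener.simulate_session(obj, small_cohort[:2], seed=1)
        assert all(len(r.log.percept_reports) == 0 for _, r in ses.iterrows())
        subj = timeline.make_session("exp1_subjective", 3)
        ses = listener.simulate_session(subj, small_cohort[:2], seed=1)
        assert all(len(r.log.detection_presses) == 0 for _, r in ses.iterrows())

    def test_event_frame_schema(self, exp2_session):
        frame = listener.logs_to_frame(exp2_session)
        assert list(frame.columns) == ["subject", "trial_id", "stream",
                                       "time_s", "value"]
        assert set(frame.stream) <= {"percept", "detect", "noise"}
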