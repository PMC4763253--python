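import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from streamscore import scoring
from streamscore.scoring import (DetectionScore, ScoringConfig, ScoringError,
                                 aggregate_dprime, classify_responses,
                                 compute_hit_window, count_nonsignal_trials,
                                 percept_at, score_trial)
from streamscore.timeline import make_trial


def brute_force_classify(deviant_silences, presses, window, duration, slack=1.5):
    """Independent press-deviant matcher: enumerate every injective
    assignment of presses to deviant windows, keep the one with the most
    hits (ties: lexicographically earliest in press order)."""
    import itertools
    presses = sorted(presses)
    valid = [p for p in presses if 0 <= p <= duration + slack]
    devs = sorted(deviant_silences)
    best = None
    n_dev = len(devs)
    for assign in itertools.product(range(-1, n_dev), repeat=len(valid)):
        used = [d for d in assign if d >= 0]
        if len(set(used)) != len(used):
            continue
        if any(d >= 0 and not (0 <= p - devs[d] <= window)
               for p, d in zip(valid, assign)):
            continue
        n_hits = len(used)
        # tie-breaks mirror the documented rule: among maximal matchings,
        # earlier presses are hits, matched to the earliest free deviant
        key = (-n_hits, tuple(d == -1 for d in assign), assign)
        if best is None or key < best[0]:
            best = (key, assign)
    assign = best[1] if best else ()
    hits = sorted(devs[d] for d in assign if d >= 0)
    fas = [p for p, d in zip(valid, assign) if d == -1]
    return hits, fas


class TestHitWindow:
    def test_constant_latencies(self):
        assert compute_hit_window([0.9, 0.9, 0.9]) == pytest.approx(0.9)

    def test_twenty_step_latencies(self):
        lats = np.round(np.arange(0.1, 2.01, 0.1), 10)
        # linear-interpolation percentile: 1.9 + 0.05 * 0.1
        assert compute_hit_window(lats) == pytest.approx(1.905)

    def test_empty_rejected(self):
        with pytest.raises(ScoringError):
            compute_hit_window([])


class TestClassification:
    @pytest.fixture
    def trial(self):
        return make_trial(0, 37, 4, "attend", ("early",), 800.0, seed=2)

    def test_press_inside_window_is_hit(self, trial):
        sil = trial.deviant_silence_onsets()["early"]
        cls = classify_responses(trial, [sil + 1.0])
        assert list(cls.kind) == ["hit"]
        assert cls.latency_s.iloc[0] == pytest.approx(1.0)

    def test_press_outside_window_is_sectioned_fa(self, trial):
        sil = trial.deviant_silence_onsets()["early"]
        cls = classify_responses(trial, [sil + 1.2])
        assert list(cls.kind) == ["fa"]
        assert cls.position.iloc[0] == "early"   # 2.625+1.2 < 6.25

    def test_no_presses_all_misses(self, trial):
        cells = score_trial(trial, [])
        assert cells.n_hits.sum() == 0
        assert cells.n_fa.sum() == 0
        assert cells.n_deviants.sum() == 1

    def test_second_press_in_window_is_fa(self, trial):
        sil = trial.deviant_silence_onsets()["early"]
        cls = classify_responses(trial, [sil + 0.3, sil + 0.6])
        assert list(cls.kind) == ["hit", "fa"]

    def test_out_of_range_press_dropped(self, trial):
        cls = classify_responses(trial, [trial.duration_s + 2.0, -0.5])
        assert set(cls.kind) == {"dropped"}

    def test_section_boundaries_per_length(self):
        cfg = ScoringConfig()
        assert cfg.section_boundaries(37) == pytest.approx((6.25, 12.5, 18.5))
        assert cfg.section_boundaries(35) == pytest.approx((5.75, 11.5, 17.5))
        assert cfg.section_boundaries(39) == pytest.approx((6.75, 13.5, 19.5))
        for n in (35, 37, 39):
            assert cfg.section_durations(n)["late"] == pytest.approx(6.0)

    def test_conservation_press_partition(self, trial):
        rng = np.random.default_rng(0)
        presses = np.sort(rng.uniform(-1, trial.duration_s + 3, 30))
        cls = classify_responses(trial, presses)
        assert len(cls) == 30
        assert set(cls.kind) <= {"hit", "fa", "dropped"}
        cells = score_trial(trial, presses)
        assert (cells.n_hits + (cells.n_deviants - cells.n_hits)).sum() \
            == cells.n_deviants.sum()


class TestBruteForceOracle:
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_exhaustive_matcher(self, seed):
        rng = np.random.default_rng(seed)
        duration, window = 10.0, 1.147
        n_dev = rng.integers(0, 4)
        devs = np.sort(rng.uniform(0, duration, n_dev))
        presses = np.sort(rng.uniform(0, duration + 1.5, rng.integers(0, 6)))
        matched = scoring.match_presses(devs, presses, window, duration)
        cls_hits = [p for p, kind, _ in matched if kind == "hit"]
        cls_fas = [p for p, kind, _ in matched if kind == "fa"]
        bf_hits, bf_fas = brute_force_classify(devs, presses, window, duration)
        assert len(cls_hits) == len(bf_hits)
        assert cls_fas == pytest.approx(bf_fas)


class TestNonsignalTrials:
    def test_six_seconds_no_deviant(self):
        assert count_nonsignal_trials(6.0, 0) == pytest.approx(6 / 1.147, abs=5e-4)

    def test_early_section_with_deviant(self):
        assert count_nonsignal_trials(6.25, 1) == pytest.approx(6.25 / 1.147 - 1, abs=5e-4)

    def test_window_equal_duration(self):
        cfg = ScoringConfig(hit_window_s=6.0)
        assert count_nonsignal_trials(6.0, 0, cfg) == pytest.approx(1.0)

    def test_nonpositive_count_rejected(self):
        with pytest.raises(ScoringError):
            count_nonsignal_trials(1.0, 1)


class TestDPrime:
    def test_equal_rates_give_zero_dprime(self):
        s = DetectionScore({}, 5, 10, 5, 10.0)
        assert s.dprime == pytest.approx(0.0)

    def test_half_rates_give_zero_criterion(self):
        s = DetectionScore({}, 5, 10, 5, 10.0)
        assert s.criterion == pytest.approx(0.0)

    def test_correction_applied_at_extremes(self):
        s = DetectionScore({}, 10, 10, 0, 20.0)
        assert s.hit_rate == pytest.approx(9.5 / 10)
        assert s.fa_rate == pytest.approx(0.5 / 20)

    def test_more_hits_than_deviants_rejected(self):
        with pytest.raises(ScoringError):
            DetectionScore({}, 11, 10, 0, 10.0)

    def test_fa_added_never_increases_dprime(self):
        base = DetectionScore({}, 8, 10, 3, 30.0)
        worse = DetectionScore({}, 8, 10, 4, 30.0)
        assert worse.dprime <= base.dprime

    def test_miss_to_hit_never_decreases_dprime(self):
        base = DetectionScore({}, 7, 10, 3, 30.0)
        better = DetectionScore({}, 8, 10, 3, 30.0)
        assert better.dprime >= base.dprime


class TestPerceptAt:
    reports = [(1.0, "one_stream"), (5.0, "two_streams")]

    def test_between_reports(self):
        assert percept_at(4.9, self.reports) == "one_stream"

    def test_boundary_inclusive(self):
        assert percept_at(5.0, self.reports) == "two_streams"

    def test_before_first_report(self):
        assert percept_at(0.5, self.reports) == "unreported"


class TestPerceptConditionedScoring:
    def test_deviant_assigned_percept_at_silence(self):
        trial = make_trial(0, 37, 8, "dual", ("early", "late"), 800.0, seed=1)
        sil = trial.deviant_silence_onsets()
        reports = [(1.0, "one_stream"), (9.0, "two_streams")]
        presses = [sil["early"] + 0.4, sil["late"] + 0.4]
        cells = scoring.score_trial_by_percept(trial, presses, reports)
        by = cells.set_index("percept")
        assert by.loc["one_stream", "n_deviants"] == 1
        assert by.loc["two_streams", "n_deviants"] == 1
        assert by.loc["one_stream", "n_hits"] == 1
        assert by.loc["two_streams", "n_hits"] == 1

    def test_unreported_deviants_excluded(self):
        trial = make_trial(0, 37, 8, "dual", ("early",), 800.0, seed=1)
        cells = scoring.score_trial_by_percept(trial, [], [(10.0, "one_stream")])
        assert cells.n_deviants.sum() == 0


class TestAggregation:
    def test_perfect_detector_reaches_theoretical_ceiling(self, objective_design):
        frames = []
        for t in objective_design.trials:
            if t.task != "attend" or t.delta_f != 4:
                continue
            presses = sorted(t.deviant_silence_onsets().values())
            f = score_trial(t, presses)
            f.insert(0, "subject", 0)
            frames.append(f)
        agg = aggregate_dprime(pd.concat(frames, ignore_index=True))
        early = agg[agg.position == "early"].iloc[0]
        assert early.n_deviants == 12
        assert early.n_nonsignal == pytest.approx(150 / 1.147 - 12, abs=1e-6)
        assert round(early.dprime, 1) == 4.4

    def test_switch_trials_scored_late_section_only(self):
        trial = make_trial(0, 37, 4, "switch", ("late",), 800.0, seed=2)
        cells = score_trial(trial, [])
        assert list(cells.position) == ["late"]
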