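"""Epoch features, the scoring decision tree, calibration and architecture."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import slowwave as sw
from slowwave.scoring import (
    NREM,
    REM,
    STATES,
    WAKE,
    Hypnogram,
    ScoringThresholds,
    bout_analysis,
    calibrate_thresholds,
    majority_smooth,
    score_epoch,
    score_features,
    state_amounts,
)

FS = 500.0


def sine_recording(freq_hz, n_epochs=2, emg=0.0, fs=FS):
    t = np.arange(int(n_epochs * 5 * fs)) / fs
    eeg = np.sin(2 * np.pi * freq_hz * t)
    return sw.Recording(eeg=eeg, emg=np.full_like(eeg, emg), fs=fs)


class TestEpochFeatures:
    def test_delta_sine_dominates_delta_band(self):
        feats = sw.compute_epoch_features(sine_recording(2.0))
        assert (feats["delta_power"] > feats["theta_power"]).all()
        assert (feats["emg_rms"] == 0).all()

    def test_theta_sine_dominates_theta_band(self):
        feats = sw.compute_epoch_features(sine_recording(7.0))
        assert (feats["theta_power"] > feats["delta_power"]).all()

    def test_one_record_per_complete_epoch(self):
        """A 3600-s recording at 5-s epochs yields exactly 720 records."""
        eeg = np.zeros(int(3600 * FS) + 1234)  # trailing partial epoch dropped
        rec = sw.Recording(eeg=eeg, emg=np.zeros_like(eeg), fs=FS)
        assert len(sw.compute_epoch_features(rec)) == 720

    def test_empty_recording_rejected(self):
        rec = sw.Recording(eeg=np.zeros(100), emg=np.zeros(100), fs=FS)
        with pytest.raises(ValueError):
            sw.compute_epoch_features(rec)


class TestScoreEpoch:
    THR = ScoringThresholds(emg_rms=10.0, theta_delta_ratio=2.0)

    @pytest.mark.parametrize(
        "delta,theta,emg,expected",
        [
            (100.0, 10.0, 1.0, NREM),   # high delta, low EMG
            (10.0, 100.0, 1.0, REM),    # theta/delta above threshold, low EMG
            (100.0, 10.0, 50.0, WAKE),  # EMG tone wins regardless of spectra
            (10.0, 100.0, 50.0, WAKE),
            (10.0, 15.0, 1.0, NREM),    # ratio 1.5 below threshold
            (0.0, 0.0, 1.0, NREM),      # degenerate zero-power -> NREM
        ],
    )
    def test_decision_tree(self, delta, theta, emg, expected):
        feats = {"delta_power": delta, "theta_power": theta, "emg_rms": emg}
        assert score_epoch(feats, self.THR) == expected

    def test_vectorized_scoring_matches_per_epoch(self):
        rng = np.random.default_rng(2)
        n = 300
        feats = pd.DataFrame(
            {
                "delta_power": rng.uniform(0, 100, n),
                "theta_power": rng.uniform(0, 100, n),
                "total_power": np.ones(n),
                "eeg_amplitude": np.ones(n),
                "emg_rms": rng.uniform(0, 20, n),
            }
        )
        hyp = score_features(feats, self.THR)
        expected = [score_epoch(feats.iloc[i], self.THR) for i in range(n)]
        assert list(hyp.states) == expected


class TestCalibration:
    @staticmethod
    def brute_force_two_means(values):
        """Optimal 1-D 2-means by enumerating every split of the sorted sample."""
        v = np.sort(values)
        best, best_cost = None, np.inf
        for i in range(1, v.size):
            lo, hi = v[:i], v[i:]
            cost = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
            if cost < best_cost:
                best_cost, best = cost, (lo.mean(), hi.mean())
        return best

    def _features(self, emg):
        n = len(emg)
        return pd.DataFrame(
            {
                "delta_power": np.ones(n),
                "theta_power": np.ones(n),
                "total_power": np.ones(n),
                "eeg_amplitude": np.ones(n),
                "emg_rms": emg,
            }
        )

    def test_bimodal_threshold_between_modes(self):
        """Two well-separated EMG modes: threshold lands between them and
        matches the brute-force optimal 2-means midpoint."""
        rng = np.random.default_rng(5)
        emg = np.concatenate([rng.normal(5, 0.5, 300), rng.normal(30, 3, 200)])
        thr = calibrate_thresholds(self._features(emg))
        assert 8 < thr.emg_rms < 27
        lo, hi = self.brute_force_two_means(emg)
        assert thr.emg_rms == pytest.approx((lo + hi) / 2, rel=0.02)

    def test_degenerate_input_falls_back_with_warning(self, caplog):
        emg = np.full(200, 3.0)
        with caplog.at_level("WARNING"):
            thr = calibrate_thresholds(self._features(emg))
        assert "unimodal" in caplog.text
        assert thr.emg_rms == pytest.approx(3.0)

    def test_unimodal_gaussian_falls_back_to_percentile(self, caplog):
        rng = np.random.default_rng(6)
        emg = rng.normal(10, 1, 500)
        with caplog.at_level("WARNING"):
            thr = calibrate_thresholds(self._features(emg))
        assert "unimodal" in caplog.text
        assert thr.emg_rms == pytest.approx(np.percentile(emg, 75))

    def test_too_few_epochs_rejected(self):
        with pytest.raises(ValueError):
            calibrate_thresholds(self._features(np.ones(50)))


class TestScoringRecovery:
    def test_recovers_ground_truth_labels(self, two_hour_recording):
        """Calibrated thresholds recover >= 90% of the ground-truth epoch
        labels on two hours of default synthetic data."""
        _, truth, rec = two_hour_recording
        scored = sw.score_recording(rec)
        agreement = np.mean(scored.states == truth.states)
        assert agreement >= 0.90


class TestStateAmounts:
    def test_all_wake_every_block(self):
        hyp = Hypnogram(states=np.array([WAKE] * (720 * 6), dtype=object))
        table = state_amounts(hyp, block_hours=3.0)
        wake = table[table["state"] == WAKE]
        assert (wake["percent"] == 100.0).all()
        assert (table[table["state"] != WAKE]["percent"] == 0.0).all()

    def test_24h_at_3h_blocks(self):
        n = 24 * 720
        hyp = Hypnogram(states=np.array([NREM] * n, dtype=object))
        table = state_amounts(hyp, block_hours=3.0)
        assert table["block"].nunique() == 8
        per_block = table.drop_duplicates("block")
        assert per_block["is_light"].sum() == 4  # 4 light + 4 dark

    def test_alternating_states_fifty_fifty(self):
        states = np.array([WAKE, NREM] * (720 * 3), dtype=object)
        table = state_amounts(Hypnogram(states=states), block_hours=3.0)
        by_state = table.groupby("state")["percent"].unique()
        assert by_state[WAKE] == [50.0]
        assert by_state[NREM] == [50.0]
        assert by_state[REM] == [0.0]

    def test_partial_trailing_block_dropped(self):
        # 2 complete 3-h blocks (2160 epochs each) plus a 100-epoch remainder
        hyp = Hypnogram(states=np.array([WAKE] * (2160 * 2 + 100), dtype=object))
        table = state_amounts(hyp, block_hours=3.0)
        assert table["block"].nunique() == 2

    def test_artifacts_excluded_from_denominator(self):
        states = np.array([WAKE] * 720, dtype=object)
        flags = np.zeros(720, dtype=bool)
        flags[:72] = True
        states[:72] = NREM  # artifact-flagged NREM must not count anywhere
        table = state_amounts(
            Hypnogram(states=states, artifact_flags=flags), block_hours=1.0
        )
        wake = table[table["state"] == WAKE]
        assert (wake["percent"] == 100.0).all()


class TestBouts:
    def test_spec_example(self):
        """W W N N N W: wake 2 bouts (10 s, 5 s), NREM 1 bout (15 s)."""
        hyp = Hypnogram(states=np.array([WAKE, WAKE, NREM, NREM, NREM, WAKE], dtype=object))
        stats = bout_analysis(hyp)
        assert stats.bout_count[WAKE] == 2
        assert stats.total_time_s[WAKE] == 15.0
        assert stats.mean_bout_duration_s[WAKE] == 7.5
        assert stats.bout_count[NREM] == 1
        assert stats.mean_bout_duration_s[NREM] == 15.0

    def test_single_state_single_bout(self):
        hyp = Hypnogram(states=np.array([REM] * 17, dtype=object))
        stats = bout_analysis(hyp)
        assert stats.bout_count[REM] == 1
        assert stats.mean_bout_duration_s[REM] == 17 * 5.0

    def test_alternating_states_all_short_bouts(self):
        hyp = Hypnogram(states=np.array([WAKE, NREM] * 10, dtype=object))
        stats = bout_analysis(hyp)
        assert stats.mean_bout_duration_s[WAKE] == 5.0
        assert stats.mean_bout_duration_s[NREM] == 5.0
        assert stats.bout_count[WAKE] == stats.bout_count[NREM] == 10

    def test_artifact_breaks_runs(self):
        states = np.array([WAKE] * 5, dtype=object)
        flags = np.array([False, False, True, False, False])
        stats = bout_analysis(Hypnogram(states=states, artifact_flags=flags))
        assert stats.bout_count[WAKE] == 2
        assert stats.artifact_time_s == 5.0

    @given(
        states=st.lists(st.sampled_from(STATES), min_size=1, max_size=200),
        flag_seed=st.integers(0, 2**16),
    )
    def test_bout_durations_partition_state_time(self, states, flag_seed):
        """Counts x mean durations reproduce state totals exactly, and state
        totals plus artifact time partition the recording."""
        rng = np.random.default_rng(flag_seed)
        flags = rng.random(len(states)) < 0.1
        hyp = Hypnogram(states=np.array(states, dtype=object), artifact_flags=flags)
        stats = bout_analysis(hyp)
        for s in STATES:
            assert stats.bout_count[s] * stats.mean_bout_duration_s[s] == pytest.approx(
                stats.total_time_s[s]
            )
        total = sum(stats.total_time_s.values()) + stats.artifact_time_s
        assert total == pytest.approx(hyp.duration_s)


class TestSmoothing:
    def test_isolated_epoch_relabelled(self):
        states = np.array([NREM, NREM, WAKE, NREM, NREM], dtype=object)
        out = majority_smooth(states)
        assert list(out) == [NREM] * 5

    def test_genuine_transition_untouched(self):
        states = np.array([WAKE, WAKE, NREM, NREM], dtype=object)
        assert list(majority_smooth(states)) == list(states)
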