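import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import butter, sosfreqz

from dyadsynch.io_formats import ContinuousRecording, REQUIRED_AUS
from dyadsynch.phasic_scoring import (
    EpochSet,
    average_trial_pairs,
    bandpass_filter,
    epoch_and_downsample,
    epoch_max_fau,
    fau_pain_expression,
    jackknife_outlier_mask,
    peak_to_peak_score,
    pain_expression_series,
    score_session,
)

from _oracles import naive_leave_one_out_outliers


def _sine(freq, fs=1000.0, dur=60.0):
    t = np.arange(0, dur, 1 / fs)
    return ContinuousRecording(np.sin(2 * np.pi * freq * t), fs)


class TestBandpass:
    def test_out_of_band_tone_is_attenuated(self):
        rec = _sine(10.0)
        out = bandpass_filter(rec, 0.0159, 5.0)
        mid = slice(10_000, 50_000)
        assert np.abs(out.samples[mid]).max() < 0.25 * np.abs(rec.samples[mid]).max()

    def test_constant_series_is_removed(self):
        rec = ContinuousRecording(np.full(10_000, 3.7), 1000.0)
        out = bandpass_filter(rec, 0.0159, 5.0)
        assert np.abs(out.samples).max() < 1e-6

    def test_passband_gain_matches_analytic_frequency_response(self):
        rec = _sine(0.5, dur=200.0)
        out = bandpass_filter(rec, 0.05, 1.0)
        sos = butter(2, [0.05, 1.0], btype="bandpass", fs=1000.0, output="sos")
        w, h = sosfreqz(sos, worN=[0.5], fs=1000.0)
        expected_gain = np.abs(h[0]) ** 2  # forward-backward application
        mid = slice(50_000, 150_000)
        measured = np.abs(out.samples[mid]).max()
        assert measured == pytest.approx(expected_gain, rel=0.05)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(_sine(1.0, fs=8.0), 0.05, 5.0)


class TestEpoching:
    def test_window_sample_count_and_onset_column(self):
        rec = ContinuousRecording(np.arange(12_000, dtype=float), 1000.0)
        epochs = epoch_and_downsample(rec, [5.0], (-2.0, 6.0), 100.0)
        assert epochs.data.shape == (1, 801)
        assert epochs.onset_index == 200
        assert epochs.data[0, 200] == rec.samples[5000]

    def test_event_near_edge_is_flagged_excluded(self):
        rec = ContinuousRecording(np.zeros(5000), 1000.0)
        epochs = epoch_and_downsample(rec, [1.0], (-2.0, 6.0), 100.0)
        assert epochs.excluded[0]
        assert "outside" in epochs.reasons[0]

    def test_decimation_matches_naive_stride_oracle(self, rng):
        samples = rng.normal(size=10_000)
        rec = ContinuousRecording(samples, 1000.0)
        epochs = epoch_and_downsample(rec, [3.0], (-2.0, 6.0), 100.0)
        oracle = samples[1000:9001:10]
        np.testing.assert_array_equal(epochs.data[0], oracle)


class TestJackknife:
    def test_identical_epochs_are_never_excluded(self):
        data = np.tile(np.linspace(0, 1, 50), (6, 1))
        epochs = EpochSet("heat", (-2, 6), 100.0, data, np.zeros(6, bool), [""] * 6)
        assert not jackknife_outlier_mask(epochs).any()

    def test_single_massive_spike_is_excluded(self, rng):
        data = rng.normal(size=(8, 50))
        data[3, 10] = 500.0
        epochs = EpochSet("heat", (-2, 6), 100.0, data, np.zeros(8, bool), [""] * 8)
        flags = jackknife_outlier_mask(epochs)
        assert flags[3]
        assert flags.sum() == 1

    def test_flags_equal_leave_one_out_oracle(self, rng):
        for _ in range(20):
            data = rng.standard_t(df=3, size=(10, 30))
            epochs = EpochSet("cue", (-2, 6), 100.0, data, np.zeros(10, bool), [""] * 10)
            np.testing.assert_array_equal(
                jackknife_outlier_mask(epochs, n_sd=2.5),
                naive_leave_one_out_outliers(data, 2.5),
            )

    def test_too_few_trials_warns_and_excludes_nothing(self):
        data = np.ones((2, 10))
        epochs = EpochSet("cue", (-2, 6), 100.0, data, np.zeros(2, bool), [""] * 2)
        with pytest.warns(UserWarning):
            assert not jackknife_outlier_mask(epochs).any()


class TestPeakToPeak:
    def _epochs(self, values, fs=1.0):
        data = np.asarray([values], dtype=float)
        return EpochSet("heat", (0.0, len(values) - 1), fs, data,
                        np.zeros(1, bool), [""])

    def test_hand_enumerated_example(self):
        epochs = self._epochs([0.10, 0.08, 0.20, 0.30, 0.50, 0.45, 0.40])
        score = peak_to_peak_score(epochs, 0)
        assert score.raw == pytest.approx(0.42, abs=1e-15)
        assert score.transformed == pytest.approx(np.log(1.42), abs=1e-12)

    def test_constant_epoch_scores_zero(self):
        score = peak_to_peak_score(self._epochs([0.3] * 7), 0)
        assert score.raw == 0.0 and score.transformed == 0.0

    def test_amplitude_floor(self):
        score = peak_to_peak_score(self._epochs([0.1, 0.1, 0.1, 0.1, 0.119, 0.1, 0.1]), 0)
        assert score.raw == 0.0

    def test_excluded_epoch_gives_excluded_score(self):
        epochs = self._epochs([0.0] * 7)
        epochs.excluded[0] = True
        assert peak_to_peak_score(epochs, 0).excluded

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=7, max_size=7),
        st.floats(-100, 100, allow_nan=False),
    )
    def test_translation_invariance_and_nonnegativity(self, values, shift):
        a = peak_to_peak_score(self._epochs(values), 0)
        b = peak_to_peak_score(self._epochs([v + shift for v in values]), 0)
        assert a.raw >= 0.0
        assert a.raw == pytest.approx(b.raw, abs=1e-9)


class TestPainExpression:
    def test_formula_example(self):
        vals = dict(zip(REQUIRED_AUS, [1.2, 0.5, 2.0, 0.0, 1.0, 0.3, 0.0, 0.7]))
        assert fau_pain_expression(vals) == pytest.approx(5.2, abs=1e-15)

    def test_all_zero_scores_zero(self):
        assert fau_pain_expression(dict.fromkeys(REQUIRED_AUS, 0.0)) == 0.0

    def test_missing_unit_gives_nan(self):
        vals = dict.fromkeys(REQUIRED_AUS, 1.0)
        vals["AU09_r"] = float("nan")
        assert np.isnan(fau_pain_expression(vals))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 5), min_size=8, max_size=8),
           st.integers(0, 7), st.floats(0, 2))
    def test_monotone_nondecreasing_in_every_unit(self, vals, idx, bump):
        base = dict(zip(REQUIRED_AUS, vals))
        bumped = dict(base)
        bumped[REQUIRED_AUS[idx]] = vals[idx] + bump
        assert fau_pain_expression(bumped) >= fau_pain_expression(base)

    def test_term_wise_oracle_on_random_frames(self, rng):
        for _ in range(50):
            v = rng.uniform(0, 5, 8)
            vals = dict(zip(REQUIRED_AUS, v))
            oracle = v[0] + max(v[1], v[2]) + max(v[3], v[4]) + v[5] + max(v[6], v[7])
            assert fau_pain_expression(vals) == pytest.approx(oracle, abs=1e-12)

    def test_series_composite_masks_missing_frames(self, rng):
        series = {}
        n = 30
        for au in REQUIRED_AUS:
            vals = rng.uniform(0, 2, n)
            series[au] = ContinuousRecording(vals, 20.0)
        series["AU04_r"].samples[5] = np.nan
        comp = pain_expression_series(series)
        assert np.isnan(comp.samples[5])
        assert np.isfinite(np.delete(comp.samples, 5)).all()


class TestEpochMaxFau:
    def _epochs(self, values, fs=1.0, window=(-1.0, 3.0)):
        return EpochSet("heat", window, fs, np.asarray([values], float),
                        np.zeros(1, bool), [""])

    def test_monotone_series_takes_last_in_window_frame(self):
        score = epoch_max_fau(self._epochs([0.0, 1.0, 2.0, 3.0, 4.0]), 0)
        assert score.raw == 4.0  # window is (onset, onset+3], onset at index 1

    def test_all_missing_frames_excluded(self):
        score = epoch_max_fau(self._epochs([np.nan] * 5), 0)
        assert score.excluded

    def test_equals_bruteforce_window_max(self, rng):
        for _ in range(30):
            vals = rng.uniform(0, 5, 41)
            epochs = self._epochs(vals, fs=10.0)
            score = epoch_max_fau(epochs, 0)
            onset = epochs.onset_index
            assert score.raw == pytest.approx(vals[onset + 1 : onset + 31].max())


class TestTrialPairs:
    def test_sequential_pair_means(self):
        np.testing.assert_array_equal(
            average_trial_pairs([1, 3, 5, 7, 9, 11]), [2.0, 6.0, 10.0]
        )

    def test_surviving_member_carries_pair(self):
        out = average_trial_pairs([np.nan, 4, 1, 2, 3, 4],
                                  excluded=[True, False, False, False, False, False])
        assert out[0] == 4.0

    def test_fully_excluded_pair_is_missing(self):
        out = average_trial_pairs([1, 2, 3, 4, 5, 6],
                                  excluded=[False] * 4 + [True, True])
        assert np.isnan(out[2])

    def test_matches_grouped_mean_oracle(self, rng):
        vals = rng.normal(size=6)
        np.testing.assert_allclose(
            average_trial_pairs(vals), vals.reshape(3, 2).mean(axis=1)
        )


def test_session_scoring_yields_tidy_table_with_rare_exclusions(tiny_session):
    df = score_session(tiny_session)
    assert set(df["outcome"]) == {"EDA_cue", "EDA_heat", "FAU_cue", "FAU_heat"}
    eda = df[df["outcome"].str.startswith("EDA")]
    assert (eda.loc[~eda["excluded"], "raw"] >= 0).all()
    # the 4.89 SD jack-knife rule should exclude well under one trial per
    # participant-outcome on clean synthetic data
    per_participant = df.groupby(["participant", "outcome"])["excluded"].sum()
    assert per_participant.mean() < 1.0
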