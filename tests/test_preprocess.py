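"""Epoching arithmetic, artifact metrics, rejection and condition balancing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prestim import (
    DataError,
    SubjectRecording,
    artifact_metrics,
    balance_conditions,
    epoch_trials,
    extract_window,
    reject_trials,
)
from conftest import make_trialset


def make_recording(signal, events, ratings=None, rate=250.0):
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    events = np.asarray(events)
    if ratings is None:
        ratings = np.where(np.arange(len(events)) % 2 == 0, 30.0, 70.0)
    return SubjectRecording(
        signal=signal,
        event_samples=events,
        ratings=np.asarray(ratings, dtype=float),
        site="left",
        channel_labels=tuple(f"ch{i}" for i in range(signal.shape[0])),
        sampling_rate=rate,
        subject_index=0,
    )


class TestEpochTrials:
    def test_sample_counts_for_standard_windows(self):
        rec = make_recording(np.zeros((2, 10000)), [3000, 6000])
        assert epoch_trials(rec, (-2.0, 2.0)).data.shape == (2, 2, 1000)
        # 1.25 s at 250 Hz under the half-open convention
        assert epoch_trials(rec, (-1.5, -0.25)).data.shape[-1] == 312

    def test_constant_zero_recording_gives_zero_trials(self):
        rec = make_recording(np.zeros((3, 8000)), [2500, 5000])
        assert not epoch_trials(rec, (-2.0, 2.0)).data.any()

    def test_index_arithmetic_against_source_samples(self):
        # event at 5000, window [-1.5, -0.25) -> samples 4625..4937 half-open
        sig = np.arange(10000, dtype=float)[None, :]
        rec = make_recording(sig, [5000], ratings=[30.0])
        got = epoch_trials(rec, (-1.5, -0.25)).data[0, 0]
        np.testing.assert_array_equal(got, np.arange(4625, 4937, dtype=float))

    def test_event_too_close_to_edge_names_offender(self):
        rec = make_recording(np.zeros((1, 2000)), [100, 1000], ratings=[30.0, 70.0])
        with pytest.raises(DataError, match="event indices \\[0\\]"):
            epoch_trials(rec, (-2.0, 2.0))

    def test_onset_maps_to_time_zero(self):
        rec = make_recording(np.zeros((1, 8000)), [4000], ratings=[30.0])
        ts = epoch_trials(rec, (-2.0, 2.0))
        onset_pos = np.argmin(np.abs(ts.time_axis))
        assert ts.time_axis[onset_pos] == pytest.approx(0.0)
        assert onset_pos == 500


class TestArtifactMetrics:
    def test_white_noise_metrics_are_zscored(self):
        rng = np.random.default_rng(0)
        ts = make_trialset(rng.standard_normal((40, 3, 500)))
        m = artifact_metrics(ts)
        for z in (m.low_band_z, m.high_band_z, m.jump_z):
            assert abs(z.mean()) < 1e-10
            assert z.std() == pytest.approx(1.0)
            assert np.isfinite(z).all()

    def test_injected_step_has_maximal_jump_score(self):
        rng = np.random.default_rng(1)
        data = 0.1 * rng.standard_normal((20, 2, 500))
        data[7, 1, 250] += 200.0  # single-sample 200 uV step
        m = artifact_metrics(make_trialset(data))
        assert m.jump_z.argmax() == 7

    def test_identical_trials_raise_zero_variance(self):
        data = np.ones((5, 2, 300))
        with pytest.raises(DataError, match="zero-variance"):
            artifact_metrics(make_trialset(data))

    def test_needs_two_trials(self):
        with pytest.raises(DataError):
            artifact_metrics(make_trialset(np.zeros((1, 2, 300))))


class TestRejectTrials:
    def test_infinite_threshold_is_identity(self):
        rng = np.random.default_rng(2)
        ts = make_trialset(rng.standard_normal((10, 2, 400)))
        m = artifact_metrics(ts)
        out = reject_trials(ts, m, np.inf)
        assert out.n_trials == 10

    def test_injected_artifact_trial_removed(self):
        rng = np.random.default_rng(3)
        data = 0.1 * rng.standard_normal((20, 2, 500))
        data[4, 0, 100] += 500.0
        ts = make_trialset(data)
        m = artifact_metrics(ts)
        out = reject_trials(ts, m, float(m.jump_z[4]) - 0.01)
        assert out.n_trials == 19
        assert 4 not in out.trial_index

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(4)
        ts = make_trialset(rng.standard_normal((60, 3, 400)))
        m = artifact_metrics(ts)
        out = reject_trials(ts, m, 1.0)
        table = np.column_stack([m.low_band_z, m.high_band_z, m.jump_z])
        expected = [i for i in range(60) if (table[i] <= 1.0).all()]
        np.testing.assert_array_equal(out.trial_index, expected)

    def test_all_rejected_is_error(self):
        # each trial extreme on a different metric, so every trial has a
        # positive z somewhere and a small threshold removes them all
        rng = np.random.default_rng(5)
        data = 0.1 * rng.standard_normal((2, 1, 400))
        data[0, 0, 200] += 300.0            # huge jump in trial 0
        data[1, 0, :] += 50.0 * np.sin(2 * np.pi * 5 * np.arange(400) / 250.0)
        ts = make_trialset(data)
        m = artifact_metrics(ts)
        with pytest.raises(DataError, match="all trials rejected"):
            reject_trials(ts, m, 0.5)


def brute_force_balance(ratings):
    """Independent re-derivation of the sort-and-take-ends rule."""
    order = sorted(range(len(ratings)), key=lambda i: (ratings[i], i))
    nopain = [i for i in order if ratings[i] < 50]
    pain = [i for i in order if ratings[i] > 50]
    m = min(len(nopain), len(pain))
    return sorted(nopain[:m] + pain[-m:])


class TestBalanceConditions:
    def test_already_balanced_keeps_everything(self):
        ts = make_trialset(np.zeros((6, 1, 100)), ratings=[10, 30, 45, 55, 70, 90])
        out = balance_conditions(ts)
        assert out.n_trials == 6
        assert (out.condition == "pain").sum() == 3

    def test_takes_ends_of_sorted_rating_list(self):
        ts = make_trialset(np.zeros((4, 1, 100)), ratings=[10, 55, 60, 70])
        out = balance_conditions(ts)
        assert sorted(out.ratings.tolist()) == [10, 70]

    def test_empty_class_is_error(self):
        ts = make_trialset(np.zeros((3, 1, 100)), ratings=[55, 60, 70])
        with pytest.raises(DataError, match="no-pain class is empty"):
            balance_conditions(ts)

    def test_rating_exactly_50_is_error(self):
        ts = make_trialset(np.zeros((3, 1, 100)), ratings=[30, 50, 70])
        with pytest.raises(DataError, match="exactly 50"):
            balance_conditions(ts)

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        ratings = rng.uniform(0, 100, 30)
        ratings[np.abs(ratings - 50) < 1e-9] = 49.0
        ts = make_trialset(np.zeros((30, 1, 50)), ratings=ratings)
        once = balance_conditions(ts)
        twice = balance_conditions(once)
        np.testing.assert_array_equal(once.trial_index, twice.trial_index)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(
        st.floats(min_value=0, max_value=100).filter(lambda r: abs(r - 50) > 1e-6),
        min_size=2, max_size=40,
    ).filter(lambda rs: any(r < 50 for r in rs) and any(r > 50 for r in rs)))
    def test_matches_brute_force_and_counts_equal(self, ratings):
        ts = make_trialset(np.zeros((len(ratings), 1, 20)), ratings=ratings)
        out = balance_conditions(ts)
        np.testing.assert_array_equal(out.trial_index, brute_force_balance(ratings))
        assert (out.condition == "pain").sum() == (out.condition == "nopain").sum()

    def test_selected_ratings_are_extreme(self):
        rng = np.random.default_rng(7)
        ratings = rng.uniform(0, 100, 40)
        ratings[np.abs(ratings - 50) < 1e-9] = 51.0
        ts = make_trialset(np.zeros((40, 1, 20)), ratings=ratings)
        out = balance_conditions(ts)
        kept = set(out.trial_index.tolist())
        excluded = [i for i in range(40) if i not in kept]
        kept_nopain = [ratings[i] for i in kept if ratings[i] < 50]
        kept_pain = [ratings[i] for i in kept if ratings[i] > 50]
        for i in excluded:
            if ratings[i] < 50:
                assert all(k <= ratings[i] for k in kept_nopain)
            else:
                assert all(k >= ratings[i] for k in kept_pain)


class TestExtractWindow:
    def test_window_lengths(self):
        ts = make_trialset(np.zeros((4, 2, 1000)), t0=-2.0)
        assert extract_window(ts, "pre").data.shape[-1] == 312
        assert extract_window(ts, "post").data.shape[-1] == 250

    def test_window_time_axes(self):
        ts = make_trialset(np.zeros((2, 1, 1000)), t0=-2.0)
        pre = extract_window(ts, "pre")
        assert pre.time_axis[0] == pytest.approx(-1.5)
        # 312 samples starting at -1.5 s: last sample at -1.5 + 311/250
        assert pre.time_axis[-1] == pytest.approx(-1.5 + 311 / 250.0)

    def test_short_epoch_is_error(self):
        ts = make_trialset(np.zeros((2, 1, 500)), t0=-1.0)
        with pytest.raises(DataError, match="not contained"):
            extract_window(ts, "pre")
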