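"""Epoching, automatic artifact metrics, trial rejection and condition
balancing.

All sample arithmetic is 0-based with half-open windows ``[start, end)``;
the number of samples in a window is ``rint((end - start) * rate)`` so the
stimulus-onset sample maps to time 0 and window lengths are unambiguous.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .config import PRE_WINDOW, POST_WINDOW
from .errors import DataError
from .simulate import SubjectRecording

#: Frequency bands of the automatic artifact metrics.
EOG_BAND = (1.0, 15.0)      # Hz, slow ocular activity proxy
MUSCLE_BAND = (100.0, 120.0)  # Hz, EMG proxy


@dataclass
class TrialSet:
    """Epoched multichannel trials with per-trial behavioral metadata."""

    data: np.ndarray              # trials x channels x samples, microvolt
    time_axis: np.ndarray         # seconds relative to stimulus onset
    channel_labels: tuple[str, ...]
    ratings: np.ndarray           # per-trial VAS value
    condition: np.ndarray         # per-trial {"pain", "nopain", "unassigned"}
    site: str
    sampling_rate: float
    trial_index: np.ndarray = None  # original trial order (chronological)

    def __post_init__(self):
        n = self.data.shape[0]
        if not (len(self.ratings) == len(self.condition) == n):
            raise DataError("trials, ratings and conditions must align 1:1")
        if self.trial_index is None:
            self.trial_index = np.arange(n)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def subset(self, idx) -> "TrialSet":
        idx = np.asarray(idx)
        return replace(
            self,
            data=self.data[idx],
            ratings=np.asarray(self.ratings)[idx],
            condition=np.asarray(self.condition)[idx],
            trial_index=np.asarray(self.trial_index)[idx],
        )


@dataclass
class ArtifactMetrics:
    """Per-trial artifact z-scores (zero mean, unit variance by construction)."""

    low_band_z: np.ndarray    # 1-15 Hz power, ocular proxy
    high_band_z: np.ndarray   # 100-120 Hz power, muscle proxy
    jump_z: np.ndarray        # max |successive-sample difference|

    def as_table(self) -> np.ndarray:
        return np.column_stack([self.low_band_z, self.high_band_z, self.jump_z])

    names = ("low_band", "high_band", "jump")


def epoch_trials(recording: SubjectRecording, window: tuple[float, float]) -> TrialSet:
    """Cut the continuous recording into per-event epochs.

    ``window`` is (start, end) in seconds relative to each stimulus onset,
    half-open; an event whose window does not fit inside the recording is an
    error naming the offending events.
    """
    lo, hi = window
    if not lo < hi:
        raise DataError(f"empty epoch window {window}")
    rate = recording.sampling_rate
    start_off = int(np.rint(lo * rate))
    n_samp = int(np.rint((hi - lo) * rate))
    n_total = recording.signal.shape[1]
    onsets = np.asarray(recording.event_samples)
    starts = onsets + start_off
    bad = np.flatnonzero((starts < 0) | (starts + n_samp > n_total))
    if bad.size:
        raise DataError(
            f"events too close to the recording edge for window {window}: "
            f"event indices {bad.tolist()} (onset samples {onsets[bad].tolist()})"
        )
    data = np.stack([recording.signal[:, s:s + n_samp] for s in starts])
    time_axis = lo + np.arange(n_samp) / rate
    return TrialSet(
        data=data,
        time_axis=time_axis,
        channel_labels=tuple(recording.channel_labels),
        ratings=np.asarray(recording.ratings, dtype=float).copy(),
        condition=np.array(["unassigned"] * len(onsets), dtype=object),
        site=recording.site,
        sampling_rate=rate,
    )


def _band_power(data: np.ndarray, band: tuple[float, float], rate: float) -> np.ndarray:
    """Per-trial band power: bandpass filter, per-channel variance, summed
    over channels. The band is all that is prescribed; the estimator is a
    zero-phase 4th-order Butterworth."""
    nyq = rate / 2.0
    hi = min(band[1], nyq * 0.99)
    sos = signal.butter(4, [band[0], hi], btype="bandpass", fs=rate, output="sos")
    filt = signal.sosfiltfilt(sos, data, axis=-1)
    return filt.var(axis=-1).sum(axis=-1)  # sum over channels -> per-trial scalar


def artifact_metrics(trials: TrialSet) -> ArtifactMetrics:
    """Trial-based z-scores for ocular (1-15 Hz) and muscle (100-120 Hz)
    band power and for the maximum absolute successive-sample difference."""
    if trials.n_trials < 2:
        raise DataError("artifact metrics need at least 2 trials")
    raw = {
        "low_band": _band_power(trials.data, EOG_BAND, trials.sampling_rate),
        "high_band": _band_power(trials.data, MUSCLE_BAND, trials.sampling_rate),
        "jump": np.abs(np.diff(trials.data, axis=-1)).max(axis=(-2, -1)),
    }
    z = {}
    for name, vals in raw.items():
        sd = vals.std()
        if sd == 0 or not np.isfinite(sd):
            raise DataError(f"zero-variance artifact metric '{name}' (degenerate input)")
        z[name] = (vals - vals.mean()) / sd
    return ArtifactMetrics(low_band_z=z["low_band"], high_band_z=z["high_band"], jump_z=z["jump"])


def reject_trials(trials: TrialSet, metrics: ArtifactMetrics, threshold: float) -> TrialSet:
    """Drop every trial whose any metric exceeds ``threshold`` z-units;
    removal is whole-epoch."""
    if threshold <= 0:
        raise DataError("rejection threshold must be positive")
    table = metrics.as_table()
    if table.shape[0] != trials.n_trials:
        raise DataError("metrics/trials length mismatch")
    keep = np.flatnonzero((table <= threshold).all(axis=1))
    if keep.size == 0:
        raise DataError(f"all trials rejected at threshold {threshold}")
    return trials.subset(keep)


def balance_conditions(trials: TrialSet) -> TrialSet:
    """Label trials by rating (> 50 pain, < 50 no-pain) and balance the
    classes by sorting ratings ascending and taking matching numbers from
    each end of the list: the m lowest-rated no-pain and the m highest-rated
    pain trials, m = min(class counts). Ties keep original trial order."""
    ratings = np.asarray(trials.ratings, dtype=float)
    if np.any(ratings == 50.0):
        raise DataError("a rating of exactly 50 is not classifiable (scale forbids it)")
    nopain = np.flatnonzero(ratings < 50.0)
    pain = np.flatnonzero(ratings > 50.0)
    if nopain.size == 0:
        raise DataError("no-pain class is empty (all ratings > 50)")
    if pain.size == 0:
        raise DataError("pain class is empty (all ratings < 50)")
    m = min(nopain.size, pain.size)
    nopain_sorted = nopain[np.argsort(ratings[nopain], kind="stable")]
    pain_sorted = pain[np.argsort(ratings[pain], kind="stable")]
    keep = np.sort(np.concatenate([nopain_sorted[:m], pain_sorted[-m:]]))
    out = trials.subset(keep)
    out.condition = np.where(np.asarray(out.ratings) > 50.0, "pain", "nopain").astype(object)
    return out


def extract_window(trials: TrialSet, period: str) -> TrialSet:
    """Cut the pre- ([-1.5, -0.25) s) or post-stimulus ([0, 1) s) analysis
    window out of the epoch."""
    windows = {"pre": PRE_WINDOW, "post": POST_WINDOW}
    if period not in windows:
        raise DataError(f"period must be one of {sorted(windows)}, got {period!r}")
    lo, hi = windows[period]
    rate = trials.sampling_rate
    t0 = trials.time_axis[0]
    t_end = trials.time_axis[0] + trials.data.shape[-1] / rate
    if lo < t0 - 1e-9 or hi > t_end + 1e-9:
        raise DataError(
            f"{period} window [{lo}, {hi}) not contained in epoch "
            f"[{t0}, {t_end})"
        )
    start = int(np.rint((lo - t0) * rate))
    n = int(np.rint((hi - lo) * rate))
    out = copy.copy(trials)
    out.data = trials.data[:, :, start:start + n]
    out.time_axis = lo + np.arange(n) / rate
    return out
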