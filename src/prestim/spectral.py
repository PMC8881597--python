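"""Multitaper (DPSS) power spectra — the classifier's feature space.

Power is estimated per trial and channel as the average over tapers of the
squared magnitude of the tapered discrete Fourier transform, evaluated
directly on a configurable frequency grid (default integer 1-Hz steps from
4 to 120 Hz, 117 features per channel). The grid need not coincide with FFT
bin frequencies; the transform is evaluated exactly at the requested
frequencies. Each trial is mean-removed before tapering; no further
detrending is applied. Power is averaged over the whole window — the
pre-stimulus state is not time-locked, so no time-resolved output is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import windows

from .errors import DataError
from .preprocess import TrialSet


@dataclass(frozen=True)
class Band:
    """Named frequency band with inclusive bounds in Hz."""

    name: str
    lo: float
    hi: float


#: Canonical band definitions. 25-29 Hz is intentionally unassigned: it is
#: excluded from band attribution but retained in full-spectrum decoding.
BANDS = (
    Band("theta", 4.0, 7.0),
    Band("alpha", 8.0, 12.0),
    Band("beta", 13.0, 24.0),
    Band("low_gamma", 30.0, 59.0),
    Band("high_gamma", 60.0, 120.0),
)
BAND_BY_NAME = {b.name: b for b in BANDS}


@dataclass
class SpectralFeatures:
    """Trials x channels x frequencies power array with axis metadata."""

    power: np.ndarray             # microvolt^2 / Hz, nonnegative
    freq_axis: np.ndarray         # Hz, strictly increasing
    channel_labels: tuple[str, ...]
    window_id: str                # {"pre", "post"} or free-form
    taper_count: int
    smoothing_halfwidth: float    # Hz

    def __post_init__(self):
        if self.power.shape[1:] != (len(self.channel_labels), len(self.freq_axis)):
            raise DataError("power array shape inconsistent with axis metadata")
        if np.any(np.diff(self.freq_axis) <= 0):
            raise DataError("frequency axis must be strictly increasing")
        if np.any(self.power < 0):
            raise DataError("power must be nonnegative")

    @property
    def n_trials(self) -> int:
        return self.power.shape[0]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise DataError(f"channel {label!r} not found in montage") from None


def dpss_tapers(n_samples: int, half_bandwidth: float, rate: float, k: int) -> np.ndarray:
    """Discrete prolate spheroidal sequences as a k x n_samples matrix.

    Rows are orthonormal; the first taper has no sign change. If ``k``
    exceeds the usual usable-taper count round(2 NW - 1) for the implied
    time-bandwidth product NW = (n_samples / rate) * half_bandwidth, a
    warning about increased spectral leakage is emitted (the request is
    still honored).
    """
    if k <= 0:
        raise DataError("taper count must be positive")
    if n_samples < 2:
        raise DataError("need at least 2 samples for tapering")
    nw = (n_samples / rate) * half_bandwidth
    usable = int(np.rint(2.0 * nw)) - 1
    if k > usable:
        warnings.warn(
            f"requested {k} tapers but only ~{usable} are well concentrated for "
            f"NW = {nw:.3f}; higher tapers increase spectral leakage",
            UserWarning,
            stacklevel=2,
        )
    tapers = windows.dpss(n_samples, nw, Kmax=k)
    return np.atleast_2d(tapers)


def multitaper_power(
    trials: TrialSet,
    fmin: float = 4.0,
    fmax: float = 120.0,
    half_bandwidth: float = 4.0,
    k: int = 9,
    grid_step: float = 1.0,
    window_id: str = "",
) -> SpectralFeatures:
    """Multitaper power spectrum of every trial and channel.

    For taper ``w_j`` and demeaned trial signal ``x``, the estimate at
    frequency ``f`` is ``mean_j | sum_t w_j(t) x(t) exp(-2 pi i f t / fs) |^2 / fs``.
    """
    if trials.n_trials == 0:
        raise DataError("empty trial set")
    rate = trials.sampling_rate
    if fmax > rate / 2.0:
        raise DataError(f"fmax {fmax} exceeds Nyquist {rate / 2.0}")
    n = trials.data.shape[-1]
    tapers = dpss_tapers(n, half_bandwidth, rate, k)
    freqs = np.arange(fmin, fmax + grid_step / 2.0, grid_step)
    t = np.arange(n) / rate
    # complex exponential basis evaluated exactly on the grid
    basis = np.exp(-2j * np.pi * np.outer(t, freqs))  # n x F
    data = trials.data - trials.data.mean(axis=-1, keepdims=True)
    n_trials, n_ch = data.shape[:2]
    power = np.empty((n_trials, n_ch, freqs.size))
    # chunk over trials to bound the (trials, ch, k, F) intermediate
    chunk = max(1, int(2e7 // (n_ch * k * freqs.size)))
    for s in range(0, n_trials, chunk):
        block = data[s:s + chunk]                      # b x ch x n
        tapered = block[:, :, None, :] * tapers[None, None, :, :]  # b x ch x k x n
        spec = tapered @ basis                         # b x ch x k x F, complex
        power[s:s + chunk] = (spec.real ** 2 + spec.imag ** 2).mean(axis=2) / rate
    return SpectralFeatures(
        power=power,
        freq_axis=freqs,
        channel_labels=tuple(trials.channel_labels),
        window_id=window_id,
        taper_count=k,
        smoothing_halfwidth=half_bandwidth,
    )


def band_select(features: SpectralFeatures, band) -> SpectralFeatures:
    """Restrict features to grid frequencies inside a band (inclusive bounds).

    ``band`` may be a :class:`Band`, a band name, or an explicit ``(lo, hi)``
    pair in Hz.
    """
    if isinstance(band, str):
        if band not in BAND_BY_NAME:
            raise DataError(f"unknown band {band!r}; known: {sorted(BAND_BY_NAME)}")
        band = BAND_BY_NAME[band]
    if isinstance(band, Band):
        lo, hi = band.lo, band.hi
    else:
        lo, hi = band
    mask = (features.freq_axis >= lo) & (features.freq_axis <= hi)
    if not mask.any():
        raise DataError(f"band ({lo}, {hi}) Hz does not intersect the frequency grid")
    return replace(
        features,
        power=features.power[:, :, mask],
        freq_axis=features.freq_axis[mask],
    )
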