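"""Synthetic EEG cohort generator.

Produces continuous multichannel recordings with the statistical structure
the downstream analysis assumes, so that every pipeline stage can be
exercised and validated without access to real recordings:

* a 1/f^alpha Gaussian background common to all channels' statistics;
* per-trial pre-stimulus high-gamma bursts (amplitude-modulated bandpass
  noise, not pure sinusoids) whose amplitude follows a latent per-trial
  state ``g_t`` evolving as an AR(1) across trials;
* a pain/no-pain report drawn through a logistic link on ``g_t``, so the
  pre-stimulus state genuinely predicts the report;
* a standardized pain/no-pain amplitude difference ``effect_size_d`` at
  fronto-central focus channels, with a signed lateralized effect at the
  central channel contralateral (+delta) / ipsilateral (-delta) to the
  stimulated hand;
* a post-stimulus evoked gamma component whose subject-mean amplitude is
  coupled across subjects to the subject-mean pre-stimulus amplitude at
  correlation ``pre_post_coupling_rho``;
* VAS ratings drawn from class-conditional truncated normals calibrated so
  the emitted (truncated) means match the configured targets; a rating of
  exactly 50 is never emitted.

The latent per-trial states are stored in ``SubjectRecording.ground_truth``
for recovery tests only; pipeline stages never read them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import integrate, optimize, signal, stats

from .config import CohortConfig
from .errors import ConfigError, DataError
from .montage import FOCUS_CHANNELS, FOCUS_NEIGHBORS

# -- fixed generator constants (documented in docs/methods.md) ----------
#: Narrow sub-bands tiling the gamma carrier range. Bursts are emitted in
#: every sub-band; the condition effect loads on a subject-specific subset
#: (individual gamma peak frequencies vary across people).
BURST_SUBBANDS = ((66.0, 72.0), (72.0, 78.0), (78.0, 84.0),
                  (84.0, 90.0), (90.0, 96.0), (96.0, 102.0))
N_EFFECT_SUBBANDS = 2            # sub-bands carrying the class effect per subject
PRE_BURST_SUPPORT = (-1.7, -0.1)  # s, envelope support of pre-stimulus bursts
POST_BURST_SUPPORT = (0.05, 0.95)  # s, envelope support of the evoked component
BACKGROUND_RMS = 8.0             # microvolt, broadband background RMS
PRE_BURST_AMP = 18.0             # microvolt, total burst RMS at envelope peak
POST_BURST_AMP = 20.0            # microvolt, evoked component RMS at envelope peak
AMP_STATE_SIGMA = 0.2            # log-amplitude scale of the per-trial state
SUBJECT_LOG_SIGMA = 0.15         # log-amplitude scale of subject-level variation
OFFFOCUS_EFFECT = 0.4            # |effect| share at non-focus channels (random sign)
LOGISTIC_SLOPE = 2.0             # slope of the class link on the latent state
EVENT_GAP_S = 5.5                # s, inter-event spacing (stimulus + rating period)


@dataclass
class SubjectRecording:
    """Continuous recording for one subject plus per-event metadata."""

    signal: np.ndarray            # channels x samples, microvolt
    event_samples: np.ndarray     # stimulus-onset sample indices, strictly increasing
    ratings: np.ndarray           # per-event VAS value, never exactly 50
    site: str                     # "left" or "right" stimulated hand
    channel_labels: tuple[str, ...]
    sampling_rate: float
    subject_index: int
    ground_truth: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        ev = np.asarray(self.event_samples)
        if ev.size and not np.all(np.diff(ev) > 0):
            raise DataError("event samples must be strictly increasing")
        if len(self.ratings) != len(ev):
            raise DataError("one rating per event required")
        if np.any(np.asarray(self.ratings) == 50.0):
            raise DataError("a rating of exactly 50 is not representable on this scale")


# -- class link calibration --------------------------------------------

@lru_cache(maxsize=None)
def _class_link_moments(slope: float) -> tuple[float, float]:
    """Mean gap and within-class variance of a standard normal latent state
    split by a Bernoulli(sigmoid(slope * g)) class draw.

    Returns (delta, v): delta = E[g | pain] - E[g | nopain]; v = Var(g | class)
    (equal for both classes by symmetry). Computed by quadrature.
    """
    phi = stats.norm.pdf

    def sig(g):
        return 1.0 / (1.0 + np.exp(-slope * g))

    m1 = 2.0 * integrate.quad(lambda g: g * sig(g) * phi(g), -12, 12)[0]
    m2 = 2.0 * integrate.quad(lambda g: g * g * sig(g) * phi(g), -12, 12)[0]
    return 2.0 * m1, m2 - m1 * m1


def _effect_scale(d_target: float, slope: float = LOGISTIC_SLOPE) -> float:
    """Loading ``e`` of the shared latent state such that the standardized
    pain/no-pain difference of ``u + e*g`` equals ``d_target``.

    Solves e*delta / sqrt(1 + e^2 * v) = d for e in closed form.
    """
    if d_target == 0.0:
        return 0.0
    delta, v = _class_link_moments(slope)
    denom = delta * delta - d_target * d_target * v
    if denom <= 0:
        raise ConfigError(
            f"effect size {d_target} is not attainable through the class link "
            f"(requires |d| < {delta / math.sqrt(v):.3f})"
        )
    return math.copysign(math.sqrt(d_target * d_target / denom), d_target)


# -- rating distribution ------------------------------------------------

@lru_cache(maxsize=None)
def _rating_truncnorm_params(
    target_mean: float, target_sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Underlying (mu, sigma) of a truncated normal on (lo, hi) whose
    *truncated* mean equals ``target_mean`` and whose truncated SD is as
    close to ``target_sd`` as the family allows.

    The published behavioral moments describe the observed (bounded)
    ratings, so they are matched on the truncated scale; the SD target can
    be infeasible near the bounds, in which case the closest achievable SD
    is used (mean always exact).
    """
    if not lo < target_mean < hi:
        raise ConfigError(f"target mean {target_mean} outside ({lo}, {hi})")

    def trunc_moments(mu, sig):
        a, b = (lo - mu) / sig, (hi - mu) / sig
        with np.errstate(all="ignore"):
            m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
            m, v = float(m), float(v)
            if not (np.isfinite(m) and np.isfinite(v) and v >= 0):
                return np.nan, np.nan
            return m, float(np.sqrt(v))

    def sigma_for_mean(mu):
        f = lambda s: trunc_moments(mu, s)[0] - target_mean
        return optimize.brentq(f, 1e-3, 50.0 * (hi - lo), xtol=1e-10)

    span = hi - lo

    def sd_gap(mu):
        try:
            s = sigma_for_mean(mu)
        except ValueError:
            return np.inf
        sd = trunc_moments(mu, s)[1]
        return abs(sd - target_sd) if np.isfinite(sd) else np.inf

    # two-stage grid search over mu (the truncated mean is matched exactly by
    # the inner sigma solve; the grid only controls how close the SD gets)
    grid = np.linspace(lo - 2.0 * span, hi + 2.0 * span, 161)
    gaps = np.array([sd_gap(m) for m in grid])
    if not np.isfinite(gaps).any():
        raise ConfigError(
            f"no truncated normal on ({lo}, {hi}) attains mean {target_mean}")
    mu = grid[int(np.nanargmin(np.where(np.isfinite(gaps), gaps, np.nan)))]
    step = grid[1] - grid[0]
    fine = np.linspace(mu - step, mu + step, 41)
    fgaps = np.array([sd_gap(m) for m in fine])
    mu = float(fine[int(np.nanargmin(np.where(np.isfinite(fgaps), fgaps, np.nan)))])
    return mu, float(sigma_for_mean(mu))


def _draw_ratings(rng, classes, rating_params) -> np.ndarray:
    """Class-conditional truncated-normal ratings; resampled (never clipped)
    on a truncation violation, so exactly 50 can never be emitted."""
    bounds = {"nopain": (0.0, 50.0), "pain": (50.0, 100.0)}
    out = np.empty(len(classes), dtype=float)
    for cls in ("nopain", "pain"):
        idx = np.flatnonzero(classes == (cls == "pain"))
        if idx.size == 0:
            continue
        tm, ts = rating_params[cls]
        lo, hi = bounds[cls]
        mu, sig = _rating_truncnorm_params(float(tm), float(ts), lo, hi)
        a, b = (lo - mu) / sig, (hi - mu) / sig
        vals = stats.truncnorm.rvs(a, b, loc=mu, scale=sig, size=idx.size, random_state=rng)
        # the open/closed endpoints have probability zero but guard anyway
        while np.any((vals <= lo) | (vals >= hi) | (vals == 50.0)):
            bad = (vals <= lo) | (vals >= hi) | (vals == 50.0)
            vals[bad] = stats.truncnorm.rvs(
                a, b, loc=mu, scale=sig, size=int(bad.sum()), random_state=rng
            )
        out[idx] = vals
    return out


# -- signal components --------------------------------------------------

def one_over_f_noise(rng, n_channels: int, n_samples: int, rate: float,
                     exponent: float, rms: float = BACKGROUND_RMS,
                     f_floor: float = 1.0) -> np.ndarray:
    """Gaussian background with power spectrum proportional to 1/f^exponent
    above ``f_floor`` (flat below), scaled to the requested broadband RMS."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate)
    shape = np.ones_like(freqs)
    above = freqs > f_floor
    shape[above] = (f_floor / freqs[above]) ** (exponent / 2.0)
    spec = (rng.standard_normal((n_channels, freqs.size))
            + 1j * rng.standard_normal((n_channels, freqs.size))) * shape
    spec[:, 0] = 0.0  # no DC offset
    sig = np.fft.irfft(spec, n=n_samples, axis=1)
    # normalize by the *expected* RMS (Parseval), not the realized one: an
    # empirical normalizer is a random factor shared by the whole recording
    # and would induce spurious all-frequency pre/post power correlation
    has_nyquist = n_samples % 2 == 0
    interior = shape[1:-1] if has_nyquist else shape[1:]
    expected_ms = (4.0 * np.sum(interior ** 2)
                   + (shape[-1] ** 2 if has_nyquist else 0.0)) / n_samples ** 2
    sig *= rms / np.sqrt(expected_ms)
    return sig


@lru_cache(maxsize=32)
def _burst_filter(rate: float, lo: float, hi: float) -> np.ndarray:
    """FIR bandpass for one gamma sub-band."""
    numtaps = int(round(rate * 0.6)) | 1  # ~0.6 s, odd length
    return signal.firwin(numtaps, (lo, hi), pass_zero=False, fs=rate)


def _burst_waveforms(rng, n_trials: int, n_channels: int, n_samples: int,
                     rate: float) -> np.ndarray:
    """Amplitude-modulated bandpass noise per trial/channel/sub-band,
    normalized to unit RMS at the envelope peak (central half)."""
    n_bands = len(BURST_SUBBANDS)
    out = np.empty((n_trials, n_channels, n_bands, n_samples))
    env = signal.windows.hann(n_samples)
    core = slice(n_samples // 4, 3 * n_samples // 4)
    for b, (lo, hi) in enumerate(BURST_SUBBANDS):
        taps = _burst_filter(rate, lo, hi)
        noise = rng.standard_normal((n_trials, n_channels, n_samples))
        filtered = signal.filtfilt(taps, [1.0], noise, axis=-1,
                                   padlen=min(3 * len(taps), n_samples - 1))
        w = filtered * env
        peak_rms = np.sqrt(np.mean(w[..., core] ** 2, axis=-1, keepdims=True))
        peak_rms[peak_rms == 0] = 1.0
        out[:, :, b] = w / peak_rms
    return out


def _channel_effects(config: CohortConfig, site: str, rng) -> np.ndarray:
    """Per-channel target standardized pain/no-pain difference.

    Full effect at the fronto-central focus, half on the neighbor ring, and
    a smaller *randomly signed* projection elsewhere — how a subject's
    preparatory state projects to distant electrodes is idiosyncratic. The
    lateral central pair carries the signed site effect. All entries scale
    with ``effect_size_d`` so a null configuration stays null.
    """
    labels = list(config.montage)
    signs = rng.choice([-1.0, 1.0], size=len(labels))
    d = signs * (OFFFOCUS_EFFECT * config.effect_size_d)
    for ch in FOCUS_NEIGHBORS:
        if ch in labels:
            d[labels.index(ch)] = 0.5 * config.effect_size_d
    for ch in FOCUS_CHANNELS:
        if ch in labels:
            d[labels.index(ch)] = config.effect_size_d
    contra = "C6" if site == "left" else "C5"
    ipsi = "C5" if site == "left" else "C6"
    d[labels.index(contra)] = config.lateralization_delta
    d[labels.index(ipsi)] = -config.lateralization_delta
    return d


# -- main entry points --------------------------------------------------

def generate_subject(config: CohortConfig, subject_index: int) -> SubjectRecording:
    """Simulate one subject's continuous recording.

    Deterministic given ``(config.seed, subject_index)``.
    """
    if not 0 <= subject_index < config.n_subjects:
        raise ConfigError(f"subject_index {subject_index} out of range [0, {config.n_subjects})")
    rate = config.sampling_rate
    site = config.site_assignment[subject_index]
    rng = np.random.default_rng([config.seed, subject_index])

    epoch_len = config.epoch_window[1] - config.epoch_window[0]
    if PRE_BURST_SUPPORT[0] < config.epoch_window[0] or POST_BURST_SUPPORT[1] > config.epoch_window[1]:
        raise ConfigError("epoch window is shorter than the burst support")

    n_events = 2 * config.n_trials_per_condition
    if EVENT_GAP_S < epoch_len:
        raise ConfigError("inter-event gap shorter than the epoch length")
    onsets_s = (epoch_len / 2.0 + 0.5) + EVENT_GAP_S * np.arange(n_events)
    event_samples = np.round(onsets_s * rate).astype(np.int64)
    n_samples = int(event_samples[-1] + round((epoch_len / 2.0 + 0.5) * rate))

    n_ch = len(config.montage)
    sig = one_over_f_noise(rng, n_ch, n_samples, rate, config.background_exponent)

    # latent per-trial state: AR(1) with unit stationary variance
    phi = config.trial_ar1_phi
    innov = rng.standard_normal(n_events)
    g = np.empty(n_events)
    g[0] = innov[0]
    scale = math.sqrt(1.0 - phi * phi)
    for t in range(1, n_events):
        g[t] = phi * g[t - 1] + scale * innov[t]

    # class through a logistic link on the state
    p_pain = 1.0 / (1.0 + np.exp(-LOGISTIC_SLOPE * g))
    is_pain = rng.random(n_events) < p_pain
    ratings = _draw_ratings(rng, is_pain, config.rating_params)

    # subject-level coupled pre/post log-amplitudes
    rho = config.pre_post_coupling_rho
    z1, z2 = rng.standard_normal(2)
    pre_base = PRE_BURST_AMP * math.exp(SUBJECT_LOG_SIGMA * z1)
    post_base = POST_BURST_AMP * math.exp(
        SUBJECT_LOG_SIGMA * (rho * z1 + math.sqrt(1.0 - rho * rho) * z2)
    )

    # per-channel loadings reproducing the target standardized differences,
    # applied on a subject-specific subset of gamma sub-bands
    d_ch = _channel_effects(config, site, rng)
    e_ch = np.array([_effect_scale(float(dv)) for dv in d_ch])
    n_bands = len(BURST_SUBBANDS)
    effect_bands = np.zeros(n_bands, dtype=bool)
    effect_bands[rng.choice(n_bands, size=N_EFFECT_SUBBANDS, replace=False)] = True
    loading = e_ch[:, None] * effect_bands[None, :]   # channels x sub-bands

    def window_samples(support):
        start = int(round(support[0] * rate))
        n = int(round((support[1] - support[0]) * rate))
        return start, n

    pre_start, pre_n = window_samples(PRE_BURST_SUPPORT)
    post_start, post_n = window_samples(POST_BURST_SUPPORT)

    # per-trial/channel/sub-band states; the standardized class difference
    # of u + e*g equals d_ch at every sub-band carrying the effect
    u_pre = rng.standard_normal((n_events, n_ch, n_bands))
    u_post = rng.standard_normal((n_events, n_ch, n_bands))
    x_pre = u_pre + loading[None] * g[:, None, None]
    x_post = u_post + loading[None] * g[:, None, None]
    scale = 1.0 / math.sqrt(n_bands)
    amp_pre = pre_base * scale * np.exp(AMP_STATE_SIGMA * x_pre)
    amp_post = post_base * scale * np.exp(AMP_STATE_SIGMA * x_post)

    bursts_pre = _burst_waveforms(rng, n_events, n_ch, pre_n, rate)
    bursts_post = _burst_waveforms(rng, n_events, n_ch, post_n, rate)

    for t, onset in enumerate(event_samples):
        s0 = onset + pre_start
        sig[:, s0:s0 + pre_n] += np.einsum("cb,cbs->cs", amp_pre[t], bursts_pre[t])
        s1 = onset + post_start
        sig[:, s1:s1 + post_n] += np.einsum("cb,cbs->cs", amp_post[t], bursts_post[t])

    return SubjectRecording(
        signal=sig,
        event_samples=event_samples,
        ratings=ratings,
        site=site,
        channel_labels=tuple(config.montage),
        sampling_rate=rate,
        subject_index=subject_index,
        ground_truth={
            "gamma_state": g,
            "is_pain": is_pain,
            "effect_bands": effect_bands,
            "channel_effects": d_ch,
            "amp_pre": amp_pre,
            "amp_post": amp_post,
            "pre_base": pre_base,
            "post_base": post_base,
        },
    )


def generate_cohort(config: CohortConfig) -> list[SubjectRecording]:
    """Simulate all subjects; reproducible under a fixed config seed."""
    return [generate_subject(config, i) for i in range(config.n_subjects)]
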