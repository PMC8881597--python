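"""Group-level inference: permutation test of the group-mean accuracy, band
attribution of classifier weights, stimulation-site lateralization ANOVA,
pre/post correlations, per-frequency coupling, and trial-series
autocorrelation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.tsa.stattools import acf as _sm_acf

from .decoding import SubjectDecoding, svm_crossval
from .errors import DataError
from .spectral import BANDS, SpectralFeatures, band_select

logger = logging.getLogger(__name__)


@dataclass
class PermutationResult:
    observed: float               # observed group-mean accuracy
    null_distribution: np.ndarray  # per-iteration group-mean accuracies
    p_value: float                # (1 + #{null >= observed}) / (1 + n_iter)
    n_iterations: int


@dataclass
class CorrelationResult:
    r: float
    p: float
    ci95: tuple[float, float]
    n: int


@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float


@dataclass
class GroupResult:
    """Container for all group-level statistics the pipeline produces."""

    group_accuracy: dict = field(default_factory=dict)       # range -> window -> mean acc
    permutation: dict = field(default_factory=dict)          # range/window key -> PermutationResult
    per_site_accuracy: dict = field(default_factory=dict)
    band_argmax_counts: dict = field(default_factory=dict)
    band_argmax_by_subject: list = field(default_factory=list)
    site_mean_weight_maps: dict = field(default_factory=dict)
    anova: AnovaResult | None = None
    accuracy_correlation: CorrelationResult | None = None
    fcz_gamma_correlation: CorrelationResult | None = None
    per_frequency: dict | None = None
    autocorrelation: list = field(default_factory=list)
    n_significant: int = 0
    n_subjects: int = 0


# -- permutation null ---------------------------------------------------

def permutation_null(
    cohort_features: list[SpectralFeatures],
    cohort_labels: list[np.ndarray],
    n_iterations: int,
    seed: int,
    observed: float | None = None,
    k_folds: int = 5,
    **decode_kwargs,
) -> PermutationResult:
    """Permutation distribution of the group-mean decoding accuracy.

    Condition labels are randomly permuted *within each subject* (labels are
    exchangeable under the null of no pre-stimulus information) and the full
    per-subject decoding — identical settings, including fold construction —
    is rerun per iteration. The p-value uses the add-one correction
    ``(1 + #{null >= observed}) / (1 + n_iterations)`` and is therefore
    never zero.
    """
    if n_iterations < 1:
        raise DataError("n_iterations must be >= 1")
    if len(cohort_features) != len(cohort_labels):
        raise DataError("features/labels cohort length mismatch")
    rng = np.random.default_rng(seed)
    if observed is None:
        accs = [
            svm_crossval(f, y, k_folds=k_folds,
                         seed=int(rng.integers(2 ** 31)), **decode_kwargs).accuracy
            for f, y in zip(cohort_features, cohort_labels)
        ]
        observed = float(np.mean(accs))
    null = np.empty(n_iterations)
    for it in range(n_iterations):
        accs = []
        for feats, labels in zip(cohort_features, cohort_labels):
            perm = rng.permutation(np.asarray(labels))
            res = svm_crossval(
                feats, perm, k_folds=k_folds,
                seed=int(rng.integers(2 ** 31)), **decode_kwargs,
            )
            accs.append(res.accuracy)
        null[it] = np.mean(accs)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_iterations)
    return PermutationResult(
        observed=float(observed), null_distribution=null,
        p_value=float(p), n_iterations=n_iterations,
    )


# -- band attribution ---------------------------------------------------

def band_argmax_weights(
    subject_results: list[SubjectDecoding],
    bands=BANDS,
    alpha: float = 0.05,
) -> tuple[list, dict]:
    """Band containing the global maximum |weight| for each subject passing
    the individual significance filter (binomial p < alpha).

    Ties between bands are broken toward the lower-frequency band and
    logged. Returns (per-subject winners, counts per band); subjects failing
    the filter get winner None.
    """
    bands = sorted(bands, key=lambda b: b.lo)
    counts = {b.name: 0 for b in bands}
    winners = []
    for res in subject_results:
        if res.binomial_p >= alpha:
            winners.append(None)
            continue
        absw = np.abs(res.weight_map)
        if not np.any(absw > 0):
            raise DataError("all-zero weight map; band attribution undefined")
        best_name, best_val = None, -np.inf
        for b in bands:
            mask = (res.freq_axis >= b.lo) & (res.freq_axis <= b.hi)
            if not mask.any():
                continue
            val = absw[:, mask].max()
            if val > best_val:
                best_name, best_val = b.name, val
            elif val == best_val:
                logger.info(
                    "band-argmax tie between %s and %s (|w| = %g); keeping the "
                    "lower-frequency band", best_name, b.name, val,
                )
        winners.append(best_name)
        counts[best_name] += 1
    return winners, counts


# -- lateralization ANOVA ----------------------------------------------

def lateralization_anova(weights_c5, weights_c6, site) -> AnovaResult:
    """Mixed two-way ANOVA of per-subject mean high-gamma weights with a
    between-subject factor (stimulation site) and a within-subject factor
    (electrode C5 vs C6); returns the site x electrode interaction
    F(1, N - 2) and its p-value.

    A perfectly crossed pattern with zero within-cell error yields an
    infinite F (p = 0), guarded explicitly.
    """
    c5 = np.asarray(weights_c5, dtype=float)
    c6 = np.asarray(weights_c6, dtype=float)
    site = np.asarray(site)
    if not (len(c5) == len(c6) == len(site)):
        raise DataError("weights/site length mismatch")
    groups = np.unique(site)
    if len(groups) != 2:
        raise DataError(f"need exactly 2 site groups, got {list(groups)}")
    for g in groups:
        if np.sum(site == g) < 2:
            raise DataError(f"site group {g!r} has fewer than 2 subjects")
    n = len(c5)
    y = np.stack([c5, c6], axis=1)          # subjects x electrode
    grand = y.mean()
    subj_means = y.mean(axis=1)
    elec_means = y.mean(axis=0)
    ss_inter = 0.0
    ss_err = 0.0
    for g in groups:
        sel = site == g
        cell = y[sel].mean(axis=0)          # per-electrode cell means
        g_mean = y[sel].mean()
        ss_inter += sel.sum() * np.sum((cell - g_mean - elec_means + grand) ** 2)
        ss_err += np.sum((y[sel] - subj_means[sel, None] - cell[None, :] + g_mean) ** 2)
    df1, df2 = 1, n - 2
    ms_inter = ss_inter / df1
    ms_err = ss_err / df2
    scale = max(abs(ss_inter), abs(ss_err), 1.0)
    if ms_err <= 1e-300 or ss_err / scale < 1e-14:
        if ss_inter / scale < 1e-14:
            return AnovaResult(F=0.0, df1=df1, df2=df2, p=1.0)
        return AnovaResult(F=np.inf, df1=df1, df2=df2, p=0.0)
    F = ms_inter / ms_err
    p = float(stats.f.sf(F, df1, df2))
    return AnovaResult(F=float(F), df1=df1, df2=df2, p=p)


# -- correlations -------------------------------------------------------

def _pearson(x, y) -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise DataError("correlation inputs must have equal length")
    if len(x) < 3:
        raise DataError("correlation needs at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DataError("zero-variance input to correlation")
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(0.95)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue),
                             ci95=(float(ci.low), float(ci.high)), n=len(x))


def accuracy_correlation(pre_acc, post_acc) -> CorrelationResult:
    """Across-subject Pearson correlation of pre- vs post-stimulus decoding
    accuracies (two-sided t-based p)."""
    return _pearson(pre_acc, post_acc)


def subject_mean_band_power(
    features: SpectralFeatures, channel: str = "FCz", band=(60.0, 120.0)
) -> float:
    """Mean power over trials and in-band frequencies at one channel."""
    ch = features.channel_index(channel)
    sel = band_select(features, band)
    return float(sel.power[:, ch, :].mean())


def fcz_gamma_correlation(
    pre_features: list[SpectralFeatures],
    post_features: list[SpectralFeatures],
    channel: str = "FCz",
    band=(60.0, 120.0),
) -> CorrelationResult:
    """Across-subject correlation of mean pre- vs post-stimulus high-gamma
    (60-120 Hz) power at one channel (default FCz)."""
    pre = [subject_mean_band_power(f, channel, band) for f in pre_features]
    post = [subject_mean_band_power(f, channel, band) for f in post_features]
    return _pearson(pre, post)


def per_frequency_correlation(
    pre_features: list[SpectralFeatures],
    post_features: list[SpectralFeatures],
    channel: str = "FCz",
    alpha: float = 0.05,
) -> dict:
    """Per-grid-frequency across-subject correlation of subject-mean pre vs
    post power at one channel, Bonferroni-corrected over frequencies."""
    if len(pre_features) != len(post_features):
        raise DataError("pre/post cohort length mismatch")
    if len(pre_features) < 3:
        raise DataError("need at least 3 subjects")
    freqs = pre_features[0].freq_axis
    for f in list(pre_features) + list(post_features):
        if not np.array_equal(f.freq_axis, freqs):
            raise DataError("frequency grids differ across subjects/windows")
    ch_pre = [f.channel_index(channel) for f in pre_features]
    ch_post = [f.channel_index(channel) for f in post_features]
    pre = np.stack([f.power[:, c, :].mean(axis=0) for f, c in zip(pre_features, ch_pre)])
    post = np.stack([f.power[:, c, :].mean(axis=0) for f, c in zip(post_features, ch_post)])
    n_freq = len(freqs)
    threshold = alpha / n_freq
    r = np.empty(n_freq)
    p = np.empty(n_freq)
    for i in range(n_freq):
        res = stats.pearsonr(pre[:, i], post[:, i])
        r[i], p[i] = res.statistic, res.pvalue
    return {
        "freqs": freqs.copy(),
        "r": r,
        "p": p,
        "significant": p < threshold,
        "bonferroni_threshold": threshold,
        "n_frequencies": n_freq,
    }


# -- trial-series autocorrelation ---------------------------------------

def trial_autocorrelation(gamma_series, max_lag: int = 20) -> dict:
    """Sample autocorrelation of a per-trial power series at lags 1..max_lag
    with white-noise confidence-bound exceedance flags (|acf| > 1.96/sqrt(N))."""
    x = np.asarray(gamma_series, dtype=float)
    n = len(x)
    if n <= max_lag + 2:
        raise DataError(f"series length {n} too short for max_lag {max_lag}")
    if np.std(x) == 0:
        raise DataError("constant series has no defined autocorrelation")
    vals = _sm_acf(x, nlags=max_lag, fft=True)[1:]
    bound = 1.96 / np.sqrt(n)
    return {
        "lags": np.arange(1, max_lag + 1),
        "acf": vals,
        "ci_bound": float(bound),
        "exceeds": np.abs(vals) > bound,
        "n": n,
    }
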