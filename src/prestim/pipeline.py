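"""End-to-end pipeline driver.

Simulate (or read) a cohort, preprocess each subject, compute pre- and
post-stimulus multitaper spectra, decode each subject per window and per
frequency range, then run group inference. Every run is fully deterministic
given the three seeds (generation, folds, permutation) recorded in the
config, and emits a resolved copy of that config next to its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .decoding import decode_subject
from .errors import DataError, PrestimError
from .group import (
    GroupResult,
    accuracy_correlation,
    band_argmax_weights,
    fcz_gamma_correlation,
    lateralization_anova,
    per_frequency_correlation,
    permutation_null,
    trial_autocorrelation,
)
from .io import write_json
from .preprocess import (
    artifact_metrics,
    balance_conditions,
    epoch_trials,
    extract_window,
    reject_trials,
)
from .simulate import generate_subject
from .spectral import band_select, multitaper_power

logger = logging.getLogger(__name__)

#: Channel used for univariate power extraction (coupling, autocorrelation).
POWER_CHANNEL = "FCz"
HIGH_GAMMA = (60.0, 120.0)


@dataclass
class SubjectArtifacts:
    """Everything the pipeline derives for one subject."""

    subject_index: int
    site: str
    n_trials_retained: int
    n_trials_balanced: int
    decodings: dict = field(default_factory=dict)   # (window, range) -> SubjectDecoding
    features: dict = field(default_factory=dict)    # window -> balanced SpectralFeatures
    labels: np.ndarray | None = None
    features_all: dict = field(default_factory=dict)  # window -> all retained trials
    gamma_series: np.ndarray | None = None          # per-trial pre FCz high-gamma power


def _fold_seed(base: int, subject: int, window: str, rng_name: str) -> int:
    h = hashlib.sha256(f"{base}:{subject}:{window}:{rng_name}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


def process_subject(config: PipelineConfig, recording, subject_index: int) -> SubjectArtifacts:
    """Preprocess, transform and decode one subject."""
    stage = "epoch"
    try:
        trials = epoch_trials(recording, tuple(config.cohort.epoch_window))
        stage = "artifact_rejection"
        metrics = artifact_metrics(trials)
        retained = reject_trials(trials, metrics, config.rejection_threshold)
        stage = "balance"
        balanced = balance_conditions(retained)
        pos = np.flatnonzero(np.isin(retained.trial_index, balanced.trial_index))
        art = SubjectArtifacts(
            subject_index=subject_index,
            site=recording.site,
            n_trials_retained=retained.n_trials,
            n_trials_balanced=balanced.n_trials,
            labels=np.asarray(balanced.condition),
        )
        for window in ("pre", "post"):
            stage = f"spectra:{window}"
            win_trials = extract_window(retained, window)
            feats_all = multitaper_power(
                win_trials,
                fmin=config.fmin,
                fmax=config.fmax,
                half_bandwidth=config.half_bandwidth,
                k=config.n_tapers,
                grid_step=config.grid_step,
                window_id=window,
            )
            art.features_all[window] = feats_all
            art.features[window] = replace(feats_all, power=feats_all.power[pos])
            stage = f"decode:{window}"
            for rng_name, rng_bounds in config.ranges.items():
                art.decodings[(window, rng_name)] = _decorate(
                    decode_subject(
                        art.features[window],
                        art.labels,
                        frequency_range=tuple(rng_bounds),
                        k_folds=config.k_folds,
                        seed=_fold_seed(config.fold_seed, subject_index, window, rng_name),
                        standardize_mode=config.standardize,
                    ),
                    subject_index,
                    recording.site,
                )
        ch = art.features_all["pre"].channel_index(POWER_CHANNEL)
        gamma = band_select(art.features_all["pre"], HIGH_GAMMA)
        art.gamma_series = gamma.power[:, ch, :].mean(axis=1)
        return art
    except PrestimError as exc:
        raise DataError(f"stage {stage!r} failed for subject {subject_index}: {exc}") from exc


def _decorate(res, subject_index, site):
    res.subject_index = subject_index
    res.site = site
    return res


def run_pipeline(config: PipelineConfig, recordings=None, output_dir=None):
    """Run the full analysis; returns ``(GroupResult, [SubjectArtifacts])``.

    ``recordings`` defaults to a freshly simulated cohort under
    ``config.cohort``; pass a list of :class:`SubjectRecording` to analyze
    existing data instead.
    """
    t0 = time.monotonic()
    cohort = config.cohort
    subjects: list[SubjectArtifacts] = []
    for i in range(cohort.n_subjects if recordings is None else len(recordings)):
        rec = generate_subject(cohort, i) if recordings is None else recordings[i]
        subjects.append(process_subject(config, rec, i))
        logger.info("subject %d processed (%.1f s elapsed)", i, time.monotonic() - t0)

    group = GroupResult(n_subjects=len(subjects))

    # mean accuracies per window and range, and per site for the headline analysis
    for (window, rng_name) in subjects[0].decodings:
        accs = [s.decodings[(window, rng_name)].accuracy for s in subjects]
        group.group_accuracy.setdefault(window, {})[rng_name] = float(np.mean(accs))
    pre_full = [s.decodings[("pre", "full")] for s in subjects]
    for site in ("left", "right"):
        accs = [r.accuracy for r in pre_full if r.site == site]
        if accs:
            group.per_site_accuracy[site] = float(np.mean(accs))
    group.n_significant = int(sum(r.binomial_p < config.alpha for r in pre_full))

    # group permutation test on the headline (pre-stimulus, full-range) analysis
    logger.info("permutation test: %d iterations", config.n_iterations)
    feats = [band_select(s.features["pre"], config.ranges["full"]) for s in subjects]
    labels = [s.labels for s in subjects]
    group.permutation[("pre", "full")] = permutation_null(
        feats,
        labels,
        n_iterations=config.n_iterations,
        seed=config.permutation_seed,
        observed=group.group_accuracy["pre"]["full"],
        k_folds=config.k_folds,
        standardize_mode=config.standardize,
    )

    # band attribution of the pre-stimulus weight maps
    winners, counts = band_argmax_weights(pre_full, alpha=config.alpha)
    group.band_argmax_by_subject = winners
    group.band_argmax_counts = counts

    # site-mean weight maps and the C5/C6 lateralization ANOVA (significant subjects)
    sig = [r for r in pre_full if r.binomial_p < config.alpha]
    for site in ("left", "right"):
        maps = [r.weight_map for r in pre_full if r.site == site]
        if maps:
            group.site_mean_weight_maps[site] = np.mean(maps, axis=0)
    sites = np.array([r.site for r in sig])
    if len(sig) >= 4 and (sites == "left").sum() >= 2 and (sites == "right").sum() >= 2:
        c5, c6 = _mean_gamma_weights(sig)
        group.anova = lateralization_anova(c5, c6, sites)
    else:
        logger.warning("too few significant subjects per site for the lateralization ANOVA")

    # pre/post relations
    post_full = [s.decodings[("post", "full")] for s in subjects]
    if len(subjects) >= 3:
        group.accuracy_correlation = accuracy_correlation(
            [r.accuracy for r in pre_full], [r.accuracy for r in post_full])
        group.fcz_gamma_correlation = fcz_gamma_correlation(
            [s.features_all["pre"] for s in subjects],
            [s.features_all["post"] for s in subjects],
            channel=POWER_CHANNEL,
        )
        group.per_frequency = per_frequency_correlation(
            [s.features_all["pre"] for s in subjects],
            [s.features_all["post"] for s in subjects],
            channel=POWER_CHANNEL,
            alpha=config.alpha,
        )

    # trial-to-trial stability of the pre-stimulus gamma state
    for s in subjects:
        if s.gamma_series is not None and len(s.gamma_series) > 22:
            res = trial_autocorrelation(s.gamma_series, max_lag=20)
            res["subject_index"] = s.subject_index
            group.autocorrelation.append(res)

    if output_dir is not None:
        write_outputs(config, group, subjects, output_dir)
    logger.info("pipeline finished in %.1f s", time.monotonic() - t0)
    return group, subjects


def _mean_gamma_weights(results):
    """Per-subject mean high-gamma weight at C5 and C6."""
    c5, c6 = [], []
    for r in results:
        mask = (r.freq_axis >= HIGH_GAMMA[0]) & (r.freq_axis <= HIGH_GAMMA[1])
        labels = list(r.channel_labels)
        c5.append(r.weight_map[labels.index("C5"), mask].mean())
        c6.append(r.weight_map[labels.index("C6"), mask].mean())
    return np.array(c5), np.array(c6)


# -- serialization ------------------------------------------------------

def group_to_dict(config: PipelineConfig, group: GroupResult) -> dict:
    perm = group.permutation.get(("pre", "full"))
    d = {
        "n_subjects": group.n_subjects,
        "n_significant_pre_full": group.n_significant,
        "group_accuracy": group.group_accuracy,
        "per_site_accuracy": group.per_site_accuracy,
        "band_argmax_counts": group.band_argmax_counts,
        "band_argmax_by_subject": group.band_argmax_by_subject,
        "alpha": config.alpha,
        "seeds": {
            "generation": config.cohort.seed,
            "folds": config.fold_seed,
            "permutation": config.permutation_seed,
        },
    }
    if perm is not None:
        d["permutation_pre_full"] = {
            "observed": perm.observed,
            "p_value": perm.p_value,
            "n_iterations": perm.n_iterations,
            "null_mean": float(np.mean(perm.null_distribution)),
            "null_distribution": perm.null_distribution,
        }
    if group.anova is not None:
        d["lateralization_anova"] = {
            "F": group.anova.F, "df1": group.anova.df1,
            "df2": group.anova.df2, "p": group.anova.p,
        }
    for key, corr in (
        ("pre_post_accuracy_correlation", group.accuracy_correlation),
        ("fcz_high_gamma_correlation", group.fcz_gamma_correlation),
    ):
        if corr is not None:
            d[key] = {"r": corr.r, "p": corr.p, "ci95": list(corr.ci95), "n": corr.n}
    if group.per_frequency is not None:
        pf = group.per_frequency
        d["per_frequency_correlation"] = {
            "freqs": pf["freqs"], "r": pf["r"], "p": pf["p"],
            "significant": pf["significant"],
            "bonferroni_threshold": pf["bonferroni_threshold"],
        }
    if group.autocorrelation:
        d["autocorrelation"] = [
            {"subject_index": a["subject_index"], "acf": a["acf"],
             "ci_bound": a["ci_bound"], "exceeds": a["exceeds"], "n": a["n"]}
            for a in group.autocorrelation
        ]
    return d


def write_outputs(config: PipelineConfig, group: GroupResult, subjects, output_dir):
    """Write resolved config, manifest, group JSON, per-subject summary CSV
    and site-mean weight maps."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_resolved.yaml")
    cfg_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()
    write_json(
        {
            "package": "prestim",
            "version": __version__,
            "config_sha256": cfg_hash,
            "seeds": {
                "generation": config.cohort.seed,
                "folds": config.fold_seed,
                "permutation": config.permutation_seed,
            },
        },
        out / "manifest.json",
    )
    write_json(group_to_dict(config, group), out / "group.json")

    rows = []
    for s in subjects:
        for (window, rng_name), res in s.decodings.items():
            rows.append({
                "subject": s.subject_index,
                "site": s.site,
                "window": window,
                "range": rng_name,
                "n_trials": res.n_trials,
                "accuracy": res.accuracy,
                "binomial_p": res.binomial_p,
            })
    pd.DataFrame(rows).to_csv(out / "subject_summary.csv", index=False)

    # per-subject weight maps for the headline analysis, one container
    import h5py

    with h5py.File(out / "weights_pre_full.h5", "w") as h5:
        ref = subjects[0].decodings[("pre", "full")]
        h5.attrs["montage"] = list(ref.channel_labels)
        h5.create_dataset("freq_axis", data=ref.freq_axis)
        for s in subjects:
            res = s.decodings[("pre", "full")]
            ds = h5.create_dataset(f"subject_{s.subject_index:03d}", data=res.weight_map)
            ds.attrs["site"] = s.site
            ds.attrs["accuracy"] = res.accuracy
            ds.attrs["binomial_p"] = res.binomial_p

    for site, wmap in group.site_mean_weight_maps.items():
        ref = subjects[0].decodings[("pre", "full")]
        df = pd.DataFrame(wmap, index=list(ref.channel_labels),
                          columns=[f"{f:g}Hz" for f in ref.freq_axis])
        df.to_csv(out / f"weights_pre_full_{site}.csv")

    if group.per_frequency is not None:
        pf = group.per_frequency
        pd.DataFrame({
            "frequency_hz": pf["freqs"], "r": pf["r"], "p": pf["p"],
            "significant": pf["significant"],
        }).to_csv(out / "per_frequency_correlation.csv", index=False)

    if group.autocorrelation:
        rows = []
        for a in group.autocorrelation:
            for lag, (val, flag) in enumerate(zip(a["acf"], a["exceeds"]), start=1):
                rows.append({"subject": a["subject_index"], "lag": lag,
                             "acf": val, "exceeds_ci": bool(flag)})
        pd.DataFrame(rows).to_csv(out / "autocorrelation.csv", index=False)

    pd.DataFrame(
        sorted(group.band_argmax_counts.items()), columns=["band", "n_subjects"]
    ).to_csv(out / "band_argmax_counts.csv", index=False)
    return out
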