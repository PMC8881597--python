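"""File formats: HDF5 containers for recordings, trial sets and spectra;
JSON/CSV result writers; optional readers for standard continuous EEG.

All writers are atomic (write to a temporary sibling, then rename), so a
crashed run never leaves a partial container behind.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import DataError
from .preprocess import ArtifactMetrics, TrialSet
from .simulate import SubjectRecording
from .spectral import SpectralFeatures

FORMAT_VERSION = 1


def _atomic(path):
    """Return (final path, temp sibling); callers write the temp file and
    rename it into place via :func:`_finish`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    os.close(fd)
    return path, Path(tmp)


def _finish(path: Path, tmp: Path):
    os.replace(tmp, path)


# -- subject recording container ---------------------------------------

def write_recording(rec: SubjectRecording, path) -> Path:
    """One hierarchical container per subject: /signal, /events, /ratings,
    optional /ground_truth group; montage, rate and site as attributes."""
    path, tmp = _atomic(path)
    try:
        with h5py.File(tmp, "w") as h5:
            h5.attrs["format_version"] = FORMAT_VERSION
            h5.attrs["kind"] = "recording"
            h5.attrs["montage"] = list(rec.channel_labels)
            h5.attrs["sampling_rate"] = rec.sampling_rate
            h5.attrs["site"] = rec.site
            h5.attrs["subject_index"] = rec.subject_index
            h5.create_dataset("signal", data=rec.signal)
            h5.create_dataset("events", data=np.asarray(rec.event_samples, dtype=np.int64))
            h5.create_dataset("ratings", data=np.asarray(rec.ratings, dtype=float))
            if rec.ground_truth:
                grp = h5.create_group("ground_truth")
                for key, val in rec.ground_truth.items():
                    grp.create_dataset(key, data=np.asarray(val))
        _finish(path, tmp)
    finally:
        tmp.unlink(missing_ok=True)
    return path


def read_recording(path) -> SubjectRecording:
    path = Path(path)
    try:
        with h5py.File(path, "r") as h5:
            if h5.attrs.get("kind", "recording") != "recording":
                raise DataError(f"{path}: container holds {h5.attrs.get('kind')!r}, not a recording")
            gt = {}
            if "ground_truth" in h5:
                gt = {k: np.asarray(v) for k, v in h5["ground_truth"].items()}
            return SubjectRecording(
                signal=np.asarray(h5["signal"]),
                event_samples=np.asarray(h5["events"]),
                ratings=np.asarray(h5["ratings"]),
                site=str(h5.attrs["site"]),
                channel_labels=tuple(str(c) for c in h5.attrs["montage"]),
                sampling_rate=float(h5.attrs["sampling_rate"]),
                subject_index=int(h5.attrs["subject_index"]),
                ground_truth=gt,
            )
    except OSError as exc:
        raise DataError(f"cannot read container {path}: {exc}") from exc
    except KeyError as exc:
        raise DataError(f"malformed container {path}: missing {exc}") from exc


def write_cohort(recordings, directory, manifest_extra=None) -> Path:
    """Write one container per subject plus a JSON manifest listing them."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in recordings:
        name = f"subject_{rec.subject_index:03d}.h5"
        write_recording(rec, directory / name)
        entries.append({
            "file": name,
            "subject_index": rec.subject_index,
            "site": rec.site,
            "n_events": int(len(rec.event_samples)),
        })
    manifest = {"format_version": FORMAT_VERSION, "subjects": entries}
    if manifest_extra:
        manifest.update(manifest_extra)
    mpath, tmp = _atomic(directory / "cohort_manifest.json")
    try:
        tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        _finish(mpath, tmp)
    finally:
        tmp.unlink(missing_ok=True)
    return mpath


def read_cohort(directory) -> list[SubjectRecording]:
    directory = Path(directory)
    mpath = directory / "cohort_manifest.json"
    if not mpath.exists():
        raise DataError(f"no cohort manifest at {mpath}")
    try:
        manifest = json.loads(mpath.read_text())
    except json.JSONDecodeError as exc:
        raise DataError(f"malformed manifest {mpath} at offset {exc.pos}: {exc.msg}") from exc
    return [read_recording(directory / e["file"]) for e in manifest["subjects"]]


# -- trial sets and spectra ---------------------------------------------

def write_trialset(trials: TrialSet, path) -> Path:
    path, tmp = _atomic(path)
    try:
        with h5py.File(tmp, "w") as h5:
            h5.attrs["format_version"] = FORMAT_VERSION
            h5.attrs["kind"] = "trialset"
            h5.attrs["montage"] = list(trials.channel_labels)
            h5.attrs["sampling_rate"] = trials.sampling_rate
            h5.attrs["site"] = trials.site
            h5.create_dataset("data", data=trials.data)
            h5.create_dataset("time_axis", data=trials.time_axis)
            h5.create_dataset("ratings", data=np.asarray(trials.ratings, dtype=float))
            h5.create_dataset("condition", data=np.array(
                [str(c) for c in trials.condition], dtype=h5py.string_dtype()))
            h5.create_dataset("trial_index", data=np.asarray(trials.trial_index, dtype=np.int64))
        _finish(path, tmp)
    finally:
        tmp.unlink(missing_ok=True)
    return path


def read_trialset(path) -> TrialSet:
    path = Path(path)
    try:
        with h5py.File(path, "r") as h5:
            if h5.attrs.get("kind") != "trialset":
                raise DataError(f"{path}: not a trial-set container")
            return TrialSet(
                data=np.asarray(h5["data"]),
                time_axis=np.asarray(h5["time_axis"]),
                channel_labels=tuple(str(c) for c in h5.attrs["montage"]),
                ratings=np.asarray(h5["ratings"]),
                condition=np.array([c.decode() if isinstance(c, bytes) else str(c)
                                    for c in h5["condition"]], dtype=object),
                site=str(h5.attrs["site"]),
                sampling_rate=float(h5.attrs["sampling_rate"]),
                trial_index=np.asarray(h5["trial_index"]),
            )
    except OSError as exc:
        raise DataError(f"cannot read container {path}: {exc}") from exc
    except KeyError as exc:
        raise DataError(f"malformed container {path}: missing {exc}") from exc


def write_features(features: SpectralFeatures, path) -> Path:
    path, tmp = _atomic(path)
    try:
        with h5py.File(tmp, "w") as h5:
            h5.attrs["format_version"] = FORMAT_VERSION
            h5.attrs["kind"] = "features"
            h5.attrs["montage"] = list(features.channel_labels)
            h5.attrs["window_id"] = features.window_id
            h5.attrs["taper_count"] = features.taper_count
            h5.attrs["smoothing_halfwidth"] = features.smoothing_halfwidth
            h5.create_dataset("power", data=features.power)
            h5.create_dataset("freq_axis", data=features.freq_axis)
        _finish(path, tmp)
    finally:
        tmp.unlink(missing_ok=True)
    return path


def read_features(path) -> SpectralFeatures:
    path = Path(path)
    try:
        with h5py.File(path, "r") as h5:
            if h5.attrs.get("kind") != "features":
                raise DataError(f"{path}: not a spectral-features container")
            return SpectralFeatures(
                power=np.asarray(h5["power"]),
                freq_axis=np.asarray(h5["freq_axis"]),
                channel_labels=tuple(str(c) for c in h5.attrs["montage"]),
                window_id=str(h5.attrs["window_id"]),
                taper_count=int(h5.attrs["taper_count"]),
                smoothing_halfwidth=float(h5.attrs["smoothing_halfwidth"]),
            )
    except OSError as exc:
        raise DataError(f"cannot read container {path}: {exc}") from exc
    except KeyError as exc:
        raise DataError(f"malformed container {path}: missing {exc}") from exc


def features_to_csv(features: SpectralFeatures, path) -> Path:
    """Long-format export (trial, channel, frequency, power) for inspection."""
    t, c, f = features.power.shape
    trial, chan, freq = np.meshgrid(
        np.arange(t), np.arange(c), np.arange(f), indexing="ij")
    df = pd.DataFrame({
        "trial": trial.ravel(),
        "channel": np.asarray(features.channel_labels)[chan.ravel()],
        "frequency_hz": features.freq_axis[freq.ravel()],
        "power": features.power.ravel(),
    })
    path, tmp = _atomic(path)
    try:
        df.to_csv(tmp, index=False)
        _finish(path, tmp)
    finally:
        tmp.unlink(missing_ok=True)
    return path


def rejection_report(metrics: ArtifactMetrics, threshold: float, path) -> Path:
    """CSV report: trial, per-metric z, kept flag."""
    table = metrics.as_table()
    df = pd.DataFrame(table, columns=[f"z_{n}" for n in ArtifactMetrics.names])
    df.insert(0, "trial", np.arange(len(df)))
    df["kept"] = (table <= threshold).all(axis=1)
    path, tmp = _atomic(path)
    try:
        df.to_csv(tmp, index=False)
        _finish(path, tmp)
    finally:
        tmp.unlink(missing_ok=True)
    return path


def write_json(obj, path) -> Path:
    """Deterministic JSON writer (sorted keys, plain floats)."""
    path, tmp = _atomic(path)
    try:
        tmp.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True))
        _finish(path, tmp)
    finally:
        tmp.unlink(missing_ok=True)
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else repr(v)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


# -- standard continuous EEG readers ------------------------------------

def read_raw_eeg(path, events_tsv, site: str = "left", subject_index: int = 0) -> SubjectRecording:
    """Read continuous EEG from EDF or BrainVision (.vhdr) via MNE together
    with an events sidecar TSV (columns: onset_sample, rating).

    MNE is an optional dependency; install the ``eeg`` extra to use this.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - env without mne
        raise DataError("reading EDF/BrainVision requires the optional 'mne' dependency") from exc
    path = Path(path)
    suffix = path.suffix.lower()
    try:
        if suffix == ".edf":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        elif suffix == ".vhdr":
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        else:
            raise DataError(f"unsupported EEG format {suffix!r} (expected .edf or .vhdr)")
    except (OSError, ValueError) as exc:
        raise DataError(f"cannot parse {path}: {exc}") from exc
    events = pd.read_csv(events_tsv, sep="\t")
    for col in ("onset_sample", "rating"):
        if col not in events.columns:
            raise DataError(f"events sidecar {events_tsv} lacks column {col!r}")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return SubjectRecording(
        signal=data,
        event_samples=events["onset_sample"].to_numpy(dtype=np.int64),
        ratings=events["rating"].to_numpy(dtype=float),
        site=site,
        channel_labels=tuple(raw.ch_names),
        sampling_rate=float(raw.info["sfreq"]),
        subject_index=subject_index,
    )
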