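"""Electrode montages.

The default layout is a 60-channel subset of the extended 10-20 system,
covering the most central scalp positions. Four labels are load-bearing for
the analysis and must be present in any montage: FCz (fronto-central power
extraction), Cz (part of the fronto-central focus) and the lateral central
pair C5/C6 (stimulation-site lateralization).
"""

from __future__ import annotations

from .errors import ConfigError

#: Labels the analysis refers to by name.
REQUIRED_CHANNELS = ("FCz", "Cz", "C5", "C6")

#: 60-channel extended 10-20 subset (central scalp positions).
DEFAULT_MONTAGE_60 = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
)

#: Compact 16-channel montage for desk-scale simulations; keeps the
#: required channels plus a sparse covering of the scalp.
SMALL_MONTAGE_16 = (
    "Fp1", "Fp2", "F3", "Fz", "F4",
    "FC1", "FCz", "FC2",
    "C5", "C3", "Cz", "C4", "C6",
    "Pz", "O1", "O2",
)

#: Fronto-central channels carrying the planted condition effect.
FOCUS_CHANNELS = ("FCz", "Cz", "FC1", "FC2")

#: Ring of neighbors receiving half the focus effect — scalp potentials are
#: spatially smeared, so a narrow 4-electrode island would be unrealistic.
FOCUS_NEIGHBORS = ("Fz", "F1", "F2", "F3", "F4", "FC3", "FC4", "C1", "C2", "C3", "C4", "CPz")


def validate_montage(labels) -> tuple[str, ...]:
    """Check uniqueness and presence of the required labels; return a tuple."""
    labels = tuple(str(c) for c in labels)
    if len(set(labels)) != len(labels):
        dupes = sorted({c for c in labels if labels.count(c) > 1})
        raise ConfigError(f"duplicate montage labels: {dupes}")
    missing = [c for c in REQUIRED_CHANNELS if c not in labels]
    if missing:
        raise ConfigError(f"montage is missing required channels: {missing}")
    return labels
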