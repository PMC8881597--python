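"""Configuration objects for the cohort generator and the analysis pipeline.

Both configs are plain dataclasses that round-trip losslessly through YAML so
that every run can emit an exact resolved copy of its parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

from .errors import ConfigError
from .montage import DEFAULT_MONTAGE_60, validate_montage

#: Decoding windows (seconds relative to stimulus onset, half-open).
PRE_WINDOW = (-1.5, -0.25)
POST_WINDOW = (0.0, 1.0)

#: Named frequency ranges the pipeline decodes in addition to the full spectrum.
DECODING_RANGES: dict[str, tuple[float, float]] = {
    "full": (4.0, 120.0),
    "high_gamma": (60.0, 120.0),
    "theta": (4.0, 7.0),
    "theta_to_beta": (4.0, 24.0),
    "up_to_low_gamma": (4.0, 59.0),
}


def default_site_assignment(n_subjects: int) -> tuple[str, ...]:
    """Left/right hand split in the study's 20:13 proportion.

    The first ``round(n * 20/33)`` subjects are stimulated at the left hand,
    the rest at the right hand; for 33 subjects this reproduces the 20/13
    split exactly.
    """
    n_left = int(round(n_subjects * 20.0 / 33.0))
    n_left = min(max(n_left, 1), n_subjects - 1) if n_subjects >= 2 else n_subjects
    return ("left",) * n_left + ("right",) * (n_subjects - n_left)


@dataclass
class CohortConfig:
    """Parameters of the synthetic EEG cohort.

    ``effect_size_d`` is the standardized pain/no-pain difference of the
    latent pre-stimulus high-gamma amplitude state at the fronto-central
    focus channels; ``lateralization_delta`` is the signed effect planted at
    the central channel contralateral (+) and ipsilateral (-) to the
    stimulated hand. ``rating_params`` are the target moments of the emitted
    (truncated) ratings per class: (mean, SD) for no-pain on [0, 50) and for
    pain on (50, 100].
    """

    n_subjects: int = 33
    n_trials_per_condition: int = 40
    sampling_rate: float = 250.0
    montage: Sequence[str] = field(default_factory=lambda: list(DEFAULT_MONTAGE_60))
    epoch_window: tuple[float, float] = (-2.0, 2.0)
    site_assignment: Sequence[str] | None = None
    effect_size_d: float = 0.8
    lateralization_delta: float | None = None  # default 0.4 * effect_size_d
    pre_post_coupling_rho: float = 0.85
    trial_ar1_phi: float = 0.0
    rating_params: dict = field(
        default_factory=lambda: {"nopain": (40.0, 12.0), "pain": (55.2, 6.4)}
    )
    background_exponent: float = 1.0
    seed: int = 0

    K_FOLDS_MIN: int = field(default=5, repr=False)

    def __post_init__(self):
        self.montage = list(validate_montage(self.montage))
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.n_trials_per_condition < self.K_FOLDS_MIN:
            raise ConfigError(
                f"n_trials_per_condition ({self.n_trials_per_condition}) must be "
                f">= {self.K_FOLDS_MIN} so every cross-validation fold sees both classes"
            )
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be positive")
        lo, hi = self.epoch_window
        if not lo < 0.0 < hi:
            raise ConfigError("epoch_window must bracket the stimulus onset")
        if self.site_assignment is None:
            self.site_assignment = list(default_site_assignment(self.n_subjects))
        else:
            self.site_assignment = [str(s) for s in self.site_assignment]
        if len(self.site_assignment) != self.n_subjects:
            raise ConfigError("site_assignment length must equal n_subjects")
        bad = sorted(set(self.site_assignment) - {"left", "right"})
        if bad:
            raise ConfigError(f"site labels must be 'left' or 'right', got {bad}")
        if self.lateralization_delta is None:
            self.lateralization_delta = 0.4 * self.effect_size_d
        if not -1.0 < self.pre_post_coupling_rho < 1.0:
            raise ConfigError("pre_post_coupling_rho must be in (-1, 1)")
        if not -1.0 < self.trial_ar1_phi < 1.0:
            raise ConfigError("trial_ar1_phi must be in (-1, 1)")
        for cls, (lo_b, hi_b) in (("nopain", (0.0, 50.0)), ("pain", (50.0, 100.0))):
            m, s = self.rating_params[cls]
            if not lo_b < m < hi_b:
                raise ConfigError(
                    f"{cls} rating mean {m} outside its truncation bounds ({lo_b}, {hi_b})"
                )
            if s <= 0:
                raise ConfigError(f"{cls} rating SD must be positive")
        if self.background_exponent < 0:
            raise ConfigError("background_exponent must be >= 0")


@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters (generator + analysis stages)."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    pre_window: tuple[float, float] = PRE_WINDOW
    post_window: tuple[float, float] = POST_WINDOW
    fmin: float = 4.0
    fmax: float = 120.0
    grid_step: float = 1.0
    half_bandwidth: float = 4.0
    n_tapers: int = 9
    k_folds: int = 5
    rejection_threshold: float = 4.0
    n_iterations: int = 500
    alpha: float = 0.05
    standardize: str = "per_fold"
    ranges: dict = field(default_factory=lambda: dict(DECODING_RANGES))
    fold_seed: int = 12345
    permutation_seed: int = 54321
    output_dir: str | None = None

    def __post_init__(self):
        if isinstance(self.cohort, dict):
            self.cohort = CohortConfig(**self.cohort)
        e_lo, e_hi = self.cohort.epoch_window
        for name, (lo, hi) in (("pre_window", self.pre_window), ("post_window", self.post_window)):
            if not (e_lo <= lo < hi <= e_hi):
                raise ConfigError(f"{name} {(lo, hi)} not contained in epoch {self.cohort.epoch_window}")
        nyq = self.cohort.sampling_rate / 2.0
        if not 0 < self.fmin < self.fmax <= nyq:
            raise ConfigError(f"frequency range ({self.fmin}, {self.fmax}) invalid for Nyquist {nyq}")
        if self.grid_step <= 0:
            raise ConfigError("grid_step must be positive")
        if self.n_tapers < 1:
            raise ConfigError("n_tapers must be >= 1")
        if self.k_folds < 2:
            raise ConfigError("k_folds must be >= 2")
        if self.rejection_threshold <= 0:
            raise ConfigError("rejection_threshold must be positive")
        if self.n_iterations < 1:
            raise ConfigError("n_iterations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.standardize not in ("per_fold", "global"):
            raise ConfigError("standardize must be 'per_fold' or 'global'")
        self.ranges = {str(k): (float(v[0]), float(v[1])) for k, v in self.ranges.items()}

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"].pop("K_FOLDS_MIN", None)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortConfig(**d["cohort"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            d = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed config file {path}: {exc}") from exc
        if not isinstance(d, dict):
            raise ConfigError(f"config file {path} does not contain a mapping")
        return cls.from_dict(d)


def _plain(obj):
    """Recursively convert tuples and numpy scalars to YAML-friendly types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj
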