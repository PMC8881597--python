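import numpy as np
import pytest

from prestim import CohortConfig, PipelineConfig
from prestim.montage import SMALL_MONTAGE_16
from prestim.preprocess import TrialSet


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """Desk-scale cohort: 4 subjects, 16 channels, defaults otherwise."""
    return CohortConfig(
        n_subjects=4,
        n_trials_per_condition=15,
        montage=SMALL_MONTAGE_16,
        seed=424,
    )


@pytest.fixture(scope="session")
def small_pipeline_config(small_config) -> PipelineConfig:
    return PipelineConfig(cohort=small_config, n_iterations=20)


def make_trialset(data, rate=250.0, ratings=None, t0=-2.0, site="left", labels=None):
    """Assemble a TrialSet around a raw (trials, channels, samples) array."""
    data = np.asarray(data, dtype=float)
    n, n_ch, n_s = data.shape
    if labels is None:
        labels = tuple(f"ch{i}" for i in range(n_ch))
    if ratings is None:
        ratings = np.where(np.arange(n) % 2 == 0, 30.0, 70.0)
    return TrialSet(
        data=data,
        time_axis=t0 + np.arange(n_s) / rate,
        channel_labels=tuple(labels),
        ratings=np.asarray(ratings, dtype=float),
        condition=np.array(["unassigned"] * n, dtype=object),
        site=site,
        sampling_rate=rate,
    )
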