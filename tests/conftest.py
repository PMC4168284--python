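import numpy as np
import pytest

from restpredict.pipeline import extract_features
from restpredict.signal import BandpassSpec
from restpredict.synthgen import CohortConfig, generate_cohort


def tiny_signal_config(seed: int = 0, **overrides) -> CohortConfig:
    """Small cohort with a strong planted signal, for fast MVPA tests."""
    params = dict(
        n_survivors=6, n_controls=6, n_followup=3,
        n_voxels=60, n_regions=8, n_timepoints=80,
        n_informative_voxels=8, n_informative_edges=3,
        alff_effect=1.5, fc_effect=1.0, noise_sd=0.3, score_noise_sd=0.0,
        seed=seed,
    )
    params.update(overrides)
    return CohortConfig(**params)


@pytest.fixture(scope="session")
def tiny_signal_features():
    cfg = tiny_signal_config(seed=0)
    sessions, truth = generate_cohort(cfg)
    feats = extract_features(sessions, truth.region_labels,
                             BandpassSpec(tr_seconds=cfg.tr_seconds))
    return feats, truth, cfg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
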