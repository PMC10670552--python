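import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ecgqual as eq
from ecgqual.datasets import split
from ecgqual.model import ModelConfig, build_model, train

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_corpus():
    """A 300-record balanced synthetic corpus at the default 20 dB class gap."""
    return eq.make_labeled_corpus(300, 0.5, seed=5)


@pytest.fixture(scope="session")
def small_split(small_corpus):
    return split(small_corpus, (0.7, 0.15, 0.15), seed=5)


@pytest.fixture(scope="session")
def trained_small_model(small_split):
    """A model trained briefly on the small corpus; good enough to separate
    the default 20 dB gap almost perfectly."""
    tr, va, _ = small_split
    cfg = ModelConfig(epochs=12, seed=5)
    return train(build_model(cfg), tr, va, cfg)


@pytest.fixture(scope="session")
def test_corpus(small_split):
    return small_split[2]


def measured_snr_db(record) -> float:
    """Oracle: re-derive the clean phantom from the record's generation
    metadata and compute the realized SNR from the noise residual."""
    clean = eq.make_clean_ecg(10.0, record.fs, record.meta["heart_rate_bpm"],
                              seed=record.meta["seed"])
    residual = record.samples - clean.samples
    p_noise = float(np.mean(residual**2))
    if p_noise == 0.0:
        return float("inf")
    return 10.0 * np.log10(float(np.mean(clean.samples**2)) / p_noise)
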