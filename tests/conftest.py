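import numpy as np
import pytest

from ecgfusion.heartbeats import segment_beats, zscore
from ecgfusion.synthetic import (
    NO_NOISE,
    NoiseSpec,
    default_profiles,
    synthesize_record,
)


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def clean_record(profiles):
    """30 s noise-free normal-rhythm record at 128 Hz."""
    return synthesize_record(profiles["N"], 30.0, 128.0, NO_NOISE, seed=11)


@pytest.fixture(scope="session")
def noisy_record(profiles):
    """30 s normal-rhythm record with the default noise mix."""
    return synthesize_record(profiles["N"], 30.0, 128.0, NoiseSpec(), seed=11)


@pytest.fixture(scope="session")
def beat_segment(clean_record):
    """One z-scored 82-sample beat from the clean record."""
    segs = segment_beats(clean_record.samples, clean_record.fs,
                         clean_record.true_rpeaks, label="N")
    return zscore(segs[1])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
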