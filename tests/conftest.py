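import numpy as np
import pytest

from fxs_oscillo import EffectConfig, Session, SubjectMeta


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def meta():
    return SubjectMeta("m-001", "KO", "M")


@pytest.fixture
def vehicle():
    return Session("vehicle", 0)


@pytest.fixture
def quiet_cfg():
    """Small, fast generator config with every stochastic component off."""
    return EffectConfig(
        n_stim=10, baseline_s=2.0, isi_s=1.5, pink_sd=0.0, ongoing_gamma_sd=0.0,
        p20_amp=0.0, n40_amp=0.0, evoked_burst_amp=0.0, induced_burst_amp=0.0,
        artifact_rate=0.0, subject_jitter_sd=0.0, session_jitter_sd=0.0,
    )
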