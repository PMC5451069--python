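import numpy as np
import pytest

from ssvepnav import PreprocessParams, SimConfig, Simulator, preprocess_training

# Small, fast simulation geometry shared across tests: 256 Hz / 2 s epochs
# keep every invariant of the full-size setup (3 harmonics below Nyquist,
# 500 ms onset discard, integer decimation) at a fraction of the cost.
SMALL_FS = 256.0
SMALL_DUR = 2.0


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(fs=SMALL_FS, epoch_dur=SMALL_DUR, snr_db=10.0, seed=1)


@pytest.fixture(scope="session")
def small_sim(small_cfg) -> Simulator:
    return Simulator(small_cfg)


@pytest.fixture(scope="session")
def small_session(small_sim):
    """80 labelled raw trials at +10 dB SNR (enough per class to fit the
    24-dimensional feature LDA comfortably inside cross-validation folds)."""
    return small_sim.generate_session(20, seed=100)


@pytest.fixture(scope="session")
def small_params() -> PreprocessParams:
    return PreprocessParams(fs_out=128.0, online_downsample=True)


@pytest.fixture(scope="session")
def small_clean(small_session, small_params):
    clean, _ = preprocess_training(small_session, small_params)
    return clean


@pytest.fixture(scope="session")
def noise_only_session():
    """Signal-free trials (all harmonic amplitudes zero): pure pink + alpha."""
    cfg = SimConfig(
        fs=SMALL_FS, epoch_dur=SMALL_DUR, harmonic_amplitudes=(0.0, 0.0, 0.0), seed=1
    )
    return Simulator(cfg).generate_session(10, seed=100)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
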