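import numpy as np
import pytest

from bcgfusion.simulate import NoiseSpec, generate_beat_times, synthesize_record


@pytest.fixture(scope="session")
def clean_record_72bpm():
    """60 s noise-free record at a constant 72 BPM, 100 Hz."""
    beats = generate_beat_times(60.0, 72.0, hrv_sd=0.0, seed=1)
    return synthesize_record(beats, fs=100.0, ptt_s=0.2,
                             noise=NoiseSpec.silent(), duration_s=60.0,
                             subject_id="clean72")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
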