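import numpy as np
import pytest

from dbgcn.recording import RawRecording, Segment


def make_recording(data, fs=250.0, label=0, subject_id="sub", names=None):
    data = np.asarray(data, dtype=np.float64)
    names = names or [f"CH{i:03d}" for i in range(data.shape[0])]
    return RawRecording(subject_id=subject_id, label=label, sampling_rate_hz=fs,
                        channel_names=names, data=data)


def sine_recording(freq_hz, fs=250.0, duration_s=8.0, n_channels=2, amplitude=1.0):
    t = np.arange(int(round(duration_s * fs))) / fs
    row = amplitude * np.sin(2 * np.pi * freq_hz * t)
    return make_recording(np.tile(row, (n_channels, 1)), fs=fs)


def make_segment(data, fs=250.0, label=0, subject_id="sub"):
    return Segment(subject_id=subject_id, label=label, sampling_rate_hz=fs,
                   start_time_s=0.0, data=np.asarray(data, dtype=np.float64))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_recording(rng):
    return make_recording(rng.standard_normal((4, 2000)), fs=250.0)
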