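"""Shared fixtures: synthetic audio, epochs, and a tiny EDF writer."""

from __future__ import annotations

import struct

import numpy as np
import pytest

from csepnet.eeg import Epoch
from csepnet.features import EPOCH_N_SAMPLES
from csepnet.montage import MONTAGE_LABELS, N_CHANNELS
from csepnet.vocoder import AudioWaveform


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def speech_like_audio(rng):
    """2 s of syllabically modulated noise at 16 kHz (vocoder-compatible)."""
    fs = 16000.0
    n = int(2.0 * fs)
    t = np.arange(n) / fs
    carrier = rng.standard_normal(n)
    # confine energy to the 200-5000 Hz analysis band
    from scipy import signal

    sos = signal.butter(4, [150, 5500], btype="bandpass", fs=fs, output="sos")
    carrier = signal.sosfiltfilt(sos, carrier)
    # near-full modulation depth, as in natural speech envelopes
    mod = 0.5 + 0.5 * np.sin(2 * np.pi * 4.0 * t)
    return AudioWaveform(0.2 * carrier * mod, fs)


def make_epoch(data, sentence_id="sent00", condition_id="c", participant_id="S000",
               k=0):
    return Epoch(np.asarray(data, dtype=np.float64), sentence_id=sentence_id,
                 condition_id=condition_id, participant_id=participant_id,
                 epoch_id=(participant_id, condition_id, k))


@pytest.fixture
def epoch_pool(rng):
    """20 noise epochs from one participant/condition."""
    return [
        make_epoch(rng.standard_normal((N_CHANNELS, EPOCH_N_SAMPLES)), k=k)
        for k in range(20)
    ]


def write_minimal_edf(path, data_uv, rate, labels):
    """Write a minimal single-record EDF file (int16, physical range ±1000 µV).

    Synthetic fixture writer — enough of the EDF spec for reader tests.
    """
    n_ch, n_samp = data_uv.shape
    duration = n_samp / rate
    phys_min, phys_max = -1000.0, 1000.0
    dig_min, dig_max = -32768, 32767

    def pad(s, n):
        return str(s)[:n].ljust(n).encode("ascii")

    header = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("X X X", 80),
        pad("01.01.20", 8), pad("00.00.00", 8),
        pad(256 + 256 * n_ch, 8), pad("", 44), pad(1, 8),
        pad(f"{duration:g}", 8), pad(n_ch, 4),
    ])
    fields = [
        (labels, 16), (["" for _ in labels], 80), (["uV"] * n_ch, 8),
        ([f"{phys_min:g}"] * n_ch, 8), ([f"{phys_max:g}"] * n_ch, 8),
        ([str(dig_min)] * n_ch, 8), ([str(dig_max)] * n_ch, 8),
        (["" for _ in labels], 80), ([str(n_samp)] * n_ch, 8),
        (["" for _ in labels], 32),
    ]
    for vals, width in fields:
        header += b"".join(pad(v, width) for v in vals)
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    with open(path, "wb") as f:
        f.write(header)
        for ch in range(n_ch):
            dig = np.clip(np.round(data_uv[ch] * scale), dig_min, dig_max).astype("<i2")
            f.write(dig.tobytes())
    return path


@pytest.fixture
def montage_labels():
    return MONTAGE_LABELS
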