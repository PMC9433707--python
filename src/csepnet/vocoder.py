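"""Noise vocoder for spectral degradation of speech.

A noise vocoder splits speech into logarithmically spaced frequency bands,
extracts each band's temporal envelope, and re-imposes the envelopes on
band-limited Gaussian noise carriers.  Fewer bands means coarser spectral
resolution — the classic simulation of cochlear-implant hearing in
normal-hearing listeners.  Band counts of 2, 3, 4, 5 and 8 over a
200–5000 Hz analysis range define the degraded stimulus conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.io import wavfile

DEFAULT_LOW_EDGE = 200.0
DEFAULT_HIGH_EDGE = 5000.0
VOCODER_CHANNEL_CONDITIONS = (2, 3, 4, 5, 8)

#: Butterworth order for the band-pass analysis/synthesis filters.
BAND_FILTER_ORDER = 4
#: Per-band envelope low-pass cutoff (Hz); matches the stimulus-feature
#: envelope definition so one envelope serves vocoding and feature extraction.
ENVELOPE_CUTOFF = 30.0


@dataclass(frozen=True)
class AudioWaveform:
    """Mono audio: samples (nominally in [-1, 1]) at a fixed rate in Hz."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=np.float64)
        if x.ndim != 1:
            raise ValueError("AudioWaveform expects a 1-D sample array")
        if not np.all(np.isfinite(x)):
            raise ValueError("audio contains non-finite samples")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        object.__setattr__(self, "samples", x)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


@dataclass(frozen=True)
class FilterBankSpec:
    """Logarithmic (geometric) band-edge layout for the vocoder."""

    n_channels: int
    low_edge: float = DEFAULT_LOW_EDGE
    high_edge: float = DEFAULT_HIGH_EDGE
    band_edges: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.band_edges is None:
            object.__setattr__(
                self,
                "band_edges",
                _log_edges(self.n_channels, self.low_edge, self.high_edge),
            )
        edges = np.asarray(self.band_edges, dtype=np.float64)
        if len(edges) != self.n_channels + 1:
            raise ValueError("band_edges must have n_channels + 1 entries")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("band_edges must be strictly increasing")
        object.__setattr__(self, "band_edges", edges)


def _log_edges(n_channels: int, low_edge: float, high_edge: float) -> np.ndarray:
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if not 0 < low_edge < high_edge:
        raise ValueError("need 0 < low_edge < high_edge")
    return np.geomspace(low_edge, high_edge, n_channels + 1)


def design_log_filterbank(
    n_channels: int,
    low_edge: float = DEFAULT_LOW_EDGE,
    high_edge: float = DEFAULT_HIGH_EDGE,
) -> FilterBankSpec:
    """Geometrically spaced band edges from ``low_edge`` to ``high_edge``.

    Consecutive edge ratios are constant: ``(high/low) ** (1/n_channels)``.
    """
    return FilterBankSpec(n_channels, low_edge, high_edge)


def _bandpass_sos(lo: float, hi: float, rate: float) -> np.ndarray:
    return signal.butter(
        BAND_FILTER_ORDER, [lo, hi], btype="bandpass", fs=rate, output="sos"
    )


def band_envelope(x: np.ndarray, rate: float, cutoff: float = ENVELOPE_CUTOFF) -> np.ndarray:
    """Full-wave rectification followed by a zero-phase low-pass at ``cutoff``."""
    sos = signal.butter(BAND_FILTER_ORDER, cutoff, btype="lowpass", fs=rate, output="sos")
    env = signal.sosfiltfilt(sos, np.abs(x))
    return np.clip(env, 0.0, None)


def noise_vocode(audio: AudioWaveform, spec: FilterBankSpec, seed: int) -> AudioWaveform:
    """Replace each band's fine structure with envelope-modulated noise.

    Per band: band-pass the input, extract its envelope (rectify + 30 Hz
    low-pass), modulate Gaussian white noise with the envelope, band-pass the
    modulated carrier again to confine splatter, and sum across bands.  The
    output is RMS-matched to the input and has identical length and rate.
    """
    if audio.rate < 2 * spec.band_edges[-1]:
        raise ValueError(
            f"sample rate {audio.rate} Hz below Nyquist for the "
            f"{spec.band_edges[-1]} Hz band edge"
        )
    x = audio.samples
    rng = np.random.default_rng(seed)
    out = np.zeros_like(x)
    for lo, hi in zip(spec.band_edges[:-1], spec.band_edges[1:]):
        sos = _bandpass_sos(lo, hi, audio.rate)
        band = signal.sosfiltfilt(sos, x)
        env = band_envelope(band, audio.rate)
        carrier = rng.standard_normal(len(x))
        modulated = signal.sosfiltfilt(sos, env * carrier)
        out += modulated
    rms_in = np.sqrt(np.mean(x**2))
    rms_out = np.sqrt(np.mean(out**2))
    if rms_out > 0 and rms_in > 0:
        out *= rms_in / rms_out
    return AudioWaveform(out, audio.rate)


def read_wav(path) -> AudioWaveform:
    """Read a mono WAV file (PCM or float) into a float waveform in [-1, 1]."""
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    return AudioWaveform(data.astype(np.float64), float(rate))


def write_wav(path, audio: AudioWaveform) -> None:
    wavfile.write(path, int(round(audio.rate)), audio.samples.astype(np.float32))
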