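"""EEG preprocessing and stimulus-locked epoching.

The pipeline mirrors standard continuous-speech EEG practice: downsample to
256 Hz, re-reference to the channel average, band-pass 1–57 Hz with a
zero-phase Hamming-windowed sinc FIR, and cut −0.5..2.5 s epochs around
sentence-onset events (768 samples per channel at 256 Hz).

Heavy eye-artifact cleaning (ICA with manual inspection) is out of scope
here; `reject_artifacts` provides a peak-amplitude threshold instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sp_signal

from .features import EEG_RATE, EPOCH_N_SAMPLES, EPOCH_ONSET_SAMPLE
from .montage import MONTAGE_LABELS

logger = logging.getLogger(__name__)

DEFAULT_BAND = (1.0, 57.0)
#: EEGLAB-style transition bandwidths used for the FIR design (Hz).
L_TRANS_BANDWIDTH = 1.0
H_TRANS_BANDWIDTH = 6.0
DEFAULT_REJECT_THRESHOLD_UV = 150.0
EPOCH_WINDOW = (-0.5, 2.5)


@dataclass
class EEGRecording:
    """64-channel continuous EEG with stimulus-onset events.

    data is channels × samples in µV; events are (sample_index, sentence_id,
    condition_id) tuples with sample indices on this recording's time base.
    """

    data: np.ndarray
    rate: float
    channel_labels: tuple
    events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match data rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        for ev in self.events:
            if not 0 <= ev[0] < self.data.shape[1]:
                raise ValueError(f"event sample {ev[0]} outside recording bounds")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class Epoch:
    """One trial: 64 × 768 (µV) at 256 Hz, t0 = −0.5 s, onset at sample 128."""

    data: np.ndarray
    sentence_id: str
    condition_id: str
    participant_id: str
    epoch_id: tuple = ()
    t0: float = EPOCH_WINDOW[0]
    rate: float = EEG_RATE

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.shape[1] != EPOCH_N_SAMPLES:
            raise ValueError(f"epoch must have {EPOCH_N_SAMPLES} samples/channel")
        if not np.all(np.isfinite(d)):
            raise ValueError("epoch contains non-finite values")
        object.__setattr__(self, "data", d)


def _resample(rec: EEGRecording, target_rate: float) -> EEGRecording:
    if target_rate == rec.rate:
        return rec
    frac = Fraction(target_rate / rec.rate).limit_denominator(10_000)
    data = sp_signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    scale = target_rate / rec.rate
    events = [
        (int(np.floor(ev[0] * scale)), *ev[1:])
        for ev in rec.events
        if int(np.floor(ev[0] * scale)) < data.shape[1]
    ]
    return EEGRecording(data, target_rate, rec.channel_labels, events)


def average_reference(data: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous mean across channels."""
    return data - data.mean(axis=0, keepdims=True)


def bandpass_fir(
    data: np.ndarray,
    rate: float,
    band: tuple = DEFAULT_BAND,
    l_trans: float = L_TRANS_BANDWIDTH,
    h_trans: float = H_TRANS_BANDWIDTH,
) -> np.ndarray:
    """Zero-phase Hamming-windowed sinc FIR band-pass (mne firwin design)."""
    import mne

    lo, hi = band
    if not 0 < lo < hi < rate / 2:
        raise ValueError(f"band {band} must lie strictly inside (0, {rate / 2}) Hz")
    logger.info(
        "FIR band-pass %.3g-%.3g Hz, transition bandwidths %.3g/%.3g Hz, "
        "hamming window, zero-phase",
        lo, hi, l_trans, h_trans,
    )
    return mne.filter.filter_data(
        np.ascontiguousarray(data, dtype=np.float64),
        sfreq=rate,
        l_freq=lo,
        h_freq=hi,
        l_trans_bandwidth=l_trans,
        h_trans_bandwidth=h_trans,
        fir_window="hamming",
        fir_design="firwin",
        phase="zero",
        verbose="error",
    )


def preprocess(
    rec: EEGRecording,
    target_rate: float = EEG_RATE,
    band: tuple = DEFAULT_BAND,
) -> EEGRecording:
    """Downsample → average reference → band-pass FIR.

    Event sample indices are rescaled with the resampling ratio (floor),
    accepting up to one sample of onset jitter.
    """
    if target_rate > rec.rate:
        raise ValueError("target_rate must not exceed the recording rate")
    rec = _resample(rec, target_rate)
    data = average_reference(rec.data)
    data = bandpass_fir(data, target_rate, band)
    return EEGRecording(data, target_rate, rec.channel_labels, rec.events)


def extract_epochs(
    rec: EEGRecording, window: tuple = EPOCH_WINDOW, participant_id: str = ""
) -> list:
    """Cut one epoch per event; out-of-bounds windows are skipped and logged."""
    n_pre = int(round(-window[0] * rec.rate))
    n_total = int(round((window[1] - window[0]) * rec.rate))
    epochs = []
    for k, ev in enumerate(rec.events):
        onset, sentence_id, condition_id = ev[0], ev[1], ev[2]
        start = onset - n_pre
        stop = start + n_total
        if start < 0 or stop > rec.data.shape[1]:
            logger.warning(
                "skipping event %d at sample %d: window [%d, %d) outside recording",
                k, onset, start, stop,
            )
            continue
        epochs.append(
            Epoch(
                rec.data[:, start:stop].copy(),
                sentence_id=str(sentence_id),
                condition_id=str(condition_id),
                participant_id=participant_id,
                epoch_id=(participant_id, str(condition_id), k),
            )
        )
    return epochs


def reject_artifacts(epochs: list, threshold: float = DEFAULT_REJECT_THRESHOLD_UV) -> list:
    """Drop epochs containing any |value| above ``threshold`` µV."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    kept = [e for e in epochs if np.max(np.abs(e.data)) <= threshold]
    if len(kept) < len(epochs):
        logger.info("rejected %d/%d epochs above %.1f uV", len(epochs) - len(kept), len(epochs), threshold)
    return kept


def reorder_to_montage(rec: EEGRecording) -> EEGRecording:
    """Reorder channels into the packaged 64-channel montage order."""
    idx = []
    for lab in MONTAGE_LABELS:
        if lab not in rec.channel_labels:
            raise ValueError(f"montage channel {lab!r} missing from recording")
        idx.append(rec.channel_labels.index(lab))
    return EEGRecording(rec.data[idx], rec.rate, tuple(MONTAGE_LABELS), rec.events)


# ---------------------------------------------------------------------------
# Readers


def load_events_csv(path) -> list:
    """Events from a CSV with columns sample, sentence_id, condition."""
    df = pd.read_csv(path)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    return [
        (int(r["sample"]), str(r["sentence_id"]), str(r["condition"]))
        for _, r in df.iterrows()
    ]


def read_raw(path, events=None) -> EEGRecording:
    """Read an EDF/BDF recording via mne into µV with optional events."""
    import mne

    path = Path(path)
    if path.suffix.lower() == ".bdf":
        raw = mne.io.read_raw_bdf(path, preload=True, verbose="error")
    else:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # V -> uV
    return EEGRecording(data, float(raw.info["sfreq"]), tuple(raw.ch_names), events or [])


def read_matrix(path, sidecar=None, events=None) -> EEGRecording:
    """Read a plain ``.npy`` channels×samples matrix with a YAML sidecar.

    The sidecar carries ``rate``, ``labels`` and optionally ``events``
    (list of [sample, sentence_id, condition]).
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".yaml")
    meta = yaml.safe_load(sidecar.read_text())
    data = np.load(path)
    evs = events or [tuple(e) for e in meta.get("events", [])]
    evs = [(int(e[0]), str(e[1]), str(e[2])) for e in evs]
    return EEGRecording(data, float(meta["rate"]), tuple(meta["labels"]), evs)


def write_matrix(path, rec: EEGRecording, sidecar=None) -> None:
    path = Path(path)
    np.save(path, rec.data)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".yaml")
    sidecar.write_text(
        yaml.safe_dump(
            {
                "rate": float(rec.rate),
                "labels": list(rec.channel_labels),
                "events": [[int(e[0]), str(e[1]), str(e[2])] for e in rec.events],
            }
        )
    )
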