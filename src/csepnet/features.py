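"""Stimulus features on the EEG time base: ENV, PH and PHENV.

Three features of each sentence drive the neural-tracking analysis:

* **ENV** — the temporal envelope: full-wave rectification of the audio
  followed by a 30 Hz low-pass, resampled to the EEG rate (256 Hz).
* **PH** — a unit impulse train with a 1 at each phoneme onset.
* **PHENV** — the element-wise product of PH and ENV, i.e. the envelope
  amplitude sampled at phoneme onsets.

Features are computed on ``[0, duration]`` and can be placed on the epoch
time base (−0.5..2.5 s, 768 samples at 256 Hz, sentence onset at sample 128)
for direct correlation with EEG epochs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal

from .vocoder import AudioWaveform

EEG_RATE = 256.0
EPOCH_N_SAMPLES = 768
EPOCH_ONSET_SAMPLE = 128  # 0.5 s pre-stimulus at 256 Hz
FEATURE_KINDS = ("ENV", "PH", "PHENV")


def round_half_away(x) -> np.ndarray:
    """Round half away from zero; the single rounding rule for onset→sample."""
    x = np.asarray(x, dtype=np.float64)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(np.int64)


@dataclass(frozen=True)
class PhonemeOnsets:
    """Phoneme onset times (s) relative to sentence onset, strictly increasing."""

    onsets: np.ndarray
    sentence_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.onsets, dtype=np.float64)
        if t.ndim != 1:
            raise ValueError("onsets must be 1-D")
        if len(t) and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
            raise ValueError("onsets must be non-negative and strictly increasing")
        object.__setattr__(self, "onsets", t)

    def __len__(self) -> int:
        return len(self.onsets)


@dataclass(frozen=True)
class FeatureSeries:
    """A stimulus feature sampled at ``rate`` Hz."""

    values: np.ndarray
    rate: float
    kind: str
    sentence_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"kind must be one of {FEATURE_KINDS}")
        if self.kind in ("ENV", "PHENV") and np.any(v < 0):
            raise ValueError(f"{self.kind} values must be non-negative")
        if self.kind == "PH" and not np.all(np.isin(v, (0.0, 1.0))):
            raise ValueError("PH values must be 0 or 1")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


def extract_envelope(
    audio: AudioWaveform, cutoff: float = 30.0, out_rate: float = EEG_RATE
) -> FeatureSeries:
    """Temporal envelope: |x| → zero-phase low-pass at ``cutoff`` → resample.

    Output length is ``round(duration * out_rate)``.  Filter undershoot is
    clipped at zero so the envelope stays non-negative.
    """
    if cutoff >= audio.rate / 2:
        raise ValueError(f"cutoff {cutoff} Hz at or above Nyquist ({audio.rate / 2} Hz)")
    if out_rate > audio.rate:
        raise ValueError("out_rate must not exceed the audio rate")
    sos = signal.butter(4, cutoff, btype="lowpass", fs=audio.rate, output="sos")
    env = signal.sosfiltfilt(sos, np.abs(audio.samples))
    n_out = int(round_half_away(len(audio.samples) / audio.rate * out_rate))
    frac = Fraction(out_rate / audio.rate).limit_denominator(10_000)
    env = signal.resample_poly(env, frac.numerator, frac.denominator)
    if len(env) > n_out:
        env = env[:n_out]
    elif len(env) < n_out:
        env = np.pad(env, (0, n_out - len(env)), mode="edge")
    return FeatureSeries(np.clip(env, 0.0, None), out_rate, "ENV")


def onset_impulse_train(
    onsets: PhonemeOnsets, duration: float, rate: float = EEG_RATE
) -> FeatureSeries:
    """Unit impulses at ``round(onset * rate)`` in a zero sequence."""
    n = int(round_half_away(duration * rate))
    train = np.zeros(n)
    for t in onsets.onsets:
        if t >= duration:
            raise ValueError(f"onset {t} s lies at or beyond duration {duration} s")
        train[int(round_half_away(t * rate))] = 1.0
    return FeatureSeries(train, rate, "PH", onsets.sentence_id)


def phenv_product(env: FeatureSeries, ph: FeatureSeries) -> FeatureSeries:
    """PHENV: element-wise product of an ENV and a PH series."""
    if env.kind != "ENV" or ph.kind != "PH":
        raise ValueError("phenv_product expects (ENV, PH) series")
    if len(env) != len(ph) or env.rate != ph.rate:
        raise ValueError(
            f"series misaligned: lengths {len(env)}/{len(ph)}, "
            f"rates {env.rate}/{ph.rate}"
        )
    return FeatureSeries(env.values * ph.values, env.rate, "PHENV", ph.sentence_id)


def to_epoch_timebase(
    series: FeatureSeries,
    n_samples: int = EPOCH_N_SAMPLES,
    onset_sample: int = EPOCH_ONSET_SAMPLE,
) -> FeatureSeries:
    """Zero-pad a [0, duration] feature onto the −0.5..2.5 s epoch window.

    The sentence onset lands at ``onset_sample``; anything beyond the window
    is truncated.
    """
    out = np.zeros(n_samples)
    n = min(len(series.values), n_samples - onset_sample)
    out[onset_sample : onset_sample + n] = series.values[:n]
    return FeatureSeries(out, series.rate, series.kind, series.sentence_id)


# ---------------------------------------------------------------------------
# Onset annotation readers: Praat TextGrid (short or long form) and TSV.


def read_onsets(path, dialect: str = None, sentence_id: str = "") -> PhonemeOnsets:
    """Read phoneme onsets from a TextGrid or a one-column TSV of seconds.

    TextGrid: start times of non-empty intervals on the phoneme tier (the
    first interval tier whose name contains "phon", else the first interval
    tier).  TSV: column 1.  Output is sorted and deduplicated.
    """
    path = Path(path)
    if dialect is None:
        dialect = "textgrid" if path.suffix.lower() == ".textgrid" else "tsv"
    if dialect == "textgrid":
        onsets = _parse_textgrid_onsets(path.read_text(encoding="utf-8", errors="replace"))
    elif dialect == "tsv":
        onsets = _parse_tsv_onsets(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    onsets = np.unique(np.asarray(onsets, dtype=np.float64))
    return PhonemeOnsets(onsets, sentence_id or path.stem)


def _parse_tsv_onsets(path: Path) -> list:
    onsets = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            onsets.append(float(line.split("\t")[0].split()[0]))
        except ValueError:
            raise ValueError(f"{path}:{lineno}: cannot parse onset time {line!r}") from None
    return onsets


def _parse_textgrid_onsets(text: str) -> list:
    tiers = _split_textgrid_tiers(text)
    if not tiers:
        raise ValueError("TextGrid contains no IntervalTier")
    phoneme_tiers = [t for t in tiers if "phon" in t[0].lower()]
    name, intervals = (phoneme_tiers or tiers)[0]
    onsets = [xmin for xmin, _xmax, label in intervals if label.strip()]
    if not onsets:
        raise ValueError(f"phoneme tier {name!r} has no labelled intervals")
    return onsets


def _split_textgrid_tiers(text: str):
    """Return [(tier_name, [(xmin, xmax, label), ...]), ...] for interval tiers.

    Handles both the long (``item [1]: class = "IntervalTier"``) and short
    (bare-line) Praat formats by scanning tokens rather than fixed layouts.
    """
    tiers = []
    # Long format: explicit keys.
    if "class = \"IntervalTier\"" in text or "class = 'IntervalTier'" in text:
        blocks = re.split(r"item\s*\[\d+\]\s*:", text)[1:]
        for block in blocks:
            if "IntervalTier" not in block.split("\n", 3)[1 if "\n" in block else 0]:
                if "IntervalTier" not in block[:200]:
                    continue
            m = re.search(r'name\s*=\s*"([^"]*)"', block)
            name = m.group(1) if m else ""
            intervals = []
            for im in re.finditer(
                r"intervals\s*\[\d+\]\s*:\s*"
                r"xmin\s*=\s*([\d.eE+-]+)\s*"
                r"xmax\s*=\s*([\d.eE+-]+)\s*"
                r'text\s*=\s*"([^"]*)"',
                block,
            ):
                intervals.append((float(im.group(1)), float(im.group(2)), im.group(3)))
            if intervals:
                tiers.append((name, intervals))
        return tiers
    # Short format: "IntervalTier" line, then name, tmin, tmax, count,
    # then triplets of xmin / xmax / "label" lines.
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    i = 0
    while i < len(lines):
        if lines[i].strip('"') == "IntervalTier":
            try:
                name = lines[i + 1].strip('"')
                count = int(float(lines[i + 4]))
                intervals = []
                j = i + 5
                for _ in range(count):
                    intervals.append(
                        (float(lines[j]), float(lines[j + 1]), lines[j + 2].strip('"'))
                    )
                    j += 3
                tiers.append((name, intervals))
                i = j
                continue
            except (IndexError, ValueError) as exc:
                raise ValueError(f"malformed short-format TextGrid near line {i}: {exc}") from None
        i += 1
    return tiers
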