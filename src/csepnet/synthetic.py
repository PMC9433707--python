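"""Synthetic study generator: speech-like stimuli, scores and forward-modelled EEG.

The recorded study data (87 normal-hearing adults, 64-channel EEG, six
stimulus conditions) are not publicly deposited, so this module emulates the
study end to end:

* **Stimuli** — amplitude-modulated pink noise with syllabic (3–6 Hz)
  modulation; per-sentence duration ~ N(1.8, 0.2²) s and 17–22 phoneme
  onsets (mean 18.6, sd 3.9), matching the sentence corpus statistics.
* **Behavioral scores** — a logistic psychometric function of vocoder
  channel count (calibrated to the study's condition means) with
  subject-level jitter, snapped to the 2.5-step grid; the three
  never-observed levels (30.0, 37.5, 40.0) are mapped to their nearest
  allowed neighbours.  The natural condition concentrates near 99.6.
* **EEG epochs** — a forward model: a gamma-shaped biphasic cortical
  response kernel (latency ≈ 100 ms) convolved with the sentence's ENV and
  PH features, scaled by a tracking gain that grows linearly with the
  intelligibility score, injected into a 12-electrode informative subset,
  plus 1/f background noise on every channel.  Epochs are 64 × 768 at
  256 Hz with sentence onset at sample 128.

Everything regenerates bit-identically from the configuration seed, and the
generator emits the same objects the real-data path produces, so synthetic
and recorded data are interchangeable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy.special import expit

from .eeg import Epoch
from .features import (
    EEG_RATE,
    EPOCH_N_SAMPLES,
    EPOCH_ONSET_SAMPLE,
    FeatureSeries,
    PhonemeOnsets,
    extract_envelope,
    onset_impulse_train,
    phenv_product,
    to_epoch_timebase,
)
from .labels import ScoreLabel, snap_to_grid
from .montage import MONTAGE_LABELS, N_CHANNELS
from .vocoder import AudioWaveform

CONDITIONS = ("voc2", "voc3", "voc4", "voc5", "voc8", "natural")
CONDITION_CHANNELS = {"voc2": 2, "voc3": 3, "voc4": 4, "voc5": 5, "voc8": 8}

#: Left central/temporal contiguous run of montage labels used as the
#: informative subset (montage rows 8..19), chosen to exercise occlusion
#: recovery at the occlusion grid's row resolution.
DEFAULT_INFORMATIVE_CHANNELS = MONTAGE_LABELS[8:20]


@dataclass(frozen=True)
class SyntheticStudyConfig:
    n_subjects: int = 87
    conditions: tuple = CONDITIONS
    n_sentences: int = 10
    sentence_duration_mean: float = 1.8
    sentence_duration_sd: float = 0.2
    phonemes_mean: float = 18.6
    phonemes_sd: float = 3.9
    phoneme_bounds: tuple = (17, 22)
    repeats_per_sentence: int = 100
    rate: float = EEG_RATE
    audio_rate: float = 16000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_sentences, self.repeats_per_sentence) <= 0:
            raise ValueError("counts must be positive")
        if self.sentence_duration_mean <= 0:
            raise ValueError("durations must be positive")


@dataclass(frozen=True)
class ForwardModelParams:
    tracking_gain_env: float = 1.0
    tracking_gain_ph: float = 1.0
    kernel_latency: float = 0.100  # s
    kernel_width: float = 0.080  # s
    informative_channels: tuple = DEFAULT_INFORMATIVE_CHANNELS
    noise_exponent: float = 1.0
    noise_scale: float = 10.0  # µV RMS of the 1/f background, per channel
    response_scale: float = 10.0  # µV RMS of the unit-gain response at score 100

    def __post_init__(self) -> None:
        if self.tracking_gain_env < 0 or self.tracking_gain_ph < 0:
            raise ValueError("tracking gains must be >= 0")
        unknown = set(self.informative_channels) - set(MONTAGE_LABELS)
        if unknown:
            raise ValueError(f"informative channels not in montage: {sorted(unknown)}")


@dataclass(frozen=True)
class PsychometricParams:
    """Logistic intelligibility vs log2(vocoder channels), anchored to the
    study's per-condition mean scores."""

    slope: float = 2.967
    midpoint: float = 1.786  # log2(channel count) at 50 %
    subject_jitter_sd: float = 0.5  # logit scale
    natural_p: float = 0.996

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")

    def mean_p(self, condition: str) -> float:
        if condition == "natural":
            return self.natural_p
        n_ch = CONDITION_CHANNELS[condition]
        return float(expit(self.slope * (np.log2(n_ch) - self.midpoint)))


# ---------------------------------------------------------------------------
# Stimuli


def _pink_noise(shape, rng, exponent: float = 1.0) -> np.ndarray:
    """1/f^exponent noise, unit RMS along the last axis."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal(shape[:-1] + (len(freqs),))
            + 1j * rng.standard_normal(shape[:-1] + (len(freqs),))) * scale
    x = np.fft.irfft(spec, n=n, axis=-1)
    rms = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    return x / np.where(rms > 0, rms, 1.0)


def gen_sentence(cfg: SyntheticStudyConfig, sentence_id: str, seed: int):
    """One speech-like sentence: AM pink noise plus phoneme onsets.

    Returns ``(AudioWaveform, PhonemeOnsets)``.  Deterministic in
    ``(cfg.seed, sentence_id, seed)``.
    """
    rng = np.random.default_rng([cfg.seed, seed])
    dur = float(np.clip(
        rng.normal(cfg.sentence_duration_mean, cfg.sentence_duration_sd), 1.2, 2.4))
    n = int(round(dur * cfg.audio_rate))
    t = np.arange(n) / cfg.audio_rate
    carrier = _pink_noise((n,), rng)
    f1, f2 = rng.uniform(3.0, 6.0, size=2)
    ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
    mod = 0.55 + 0.3 * np.sin(2 * np.pi * f1 * t + ph1) + 0.15 * np.sin(2 * np.pi * f2 * t + ph2)
    audio = AudioWaveform(0.2 * carrier * np.clip(mod, 0.0, None), cfg.audio_rate)

    lo, hi = cfg.phoneme_bounds
    count = int(np.clip(round(rng.normal(cfg.phonemes_mean, cfg.phonemes_sd)), lo, hi))
    while True:
        onsets = np.sort(rng.uniform(0.05, dur - 0.1, size=count))
        if len(onsets) < 2 or np.min(np.diff(onsets)) > 2e-3:
            break
    return audio, PhonemeOnsets(onsets, sentence_id)


def sentence_features(audio: AudioWaveform, onsets: PhonemeOnsets) -> dict:
    """ENV/PH/PHENV for one sentence, on the 768-sample epoch time base."""
    env = extract_envelope(audio, cutoff=30.0, out_rate=EEG_RATE)
    ph = onset_impulse_train(onsets, duration=len(env) / EEG_RATE, rate=EEG_RATE)
    phenv = phenv_product(env, ph)
    return {k: to_epoch_timebase(s) for k, s in
            (("ENV", env), ("PH", ph), ("PHENV", phenv))}


# ---------------------------------------------------------------------------
# Behavioral scores


def gen_behavioral_scores(cfg: SyntheticStudyConfig,
                          psych: PsychometricParams = PsychometricParams(),
                          seed: int = None) -> pd.DataFrame:
    """Score table (participant, condition, score) on the allowed 2.5 grid."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    rows = []
    for s in range(cfg.n_subjects):
        jitter = rng.normal(0, psych.subject_jitter_sd)
        for cond in cfg.conditions:
            p = psych.mean_p(cond)
            logit = np.log(p / (1 - p)) if 0 < p < 1 else np.sign(2 * p - 1) * 20
            score = snap_to_grid(100 * expit(logit + jitter))
            rows.append({"participant": f"S{s:03d}", "condition": cond, "score": score})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Forward-modelled EEG


def response_kernel(rate: float = EEG_RATE, latency: float = 0.100,
                    width: float = 0.080) -> np.ndarray:
    """Gamma-shaped biphasic cortical impulse response, peak-normalized.

    A positive gamma lobe peaking at ``latency`` followed by a slower
    negative lobe — a minimal stand-in for an auditory evoked response.
    """
    t = np.arange(0, latency + 6 * width, 1.0 / rate)
    k = 4.0
    theta1 = latency / (k - 1)
    theta2 = (latency + 1.5 * width) / (k - 1)
    g1 = t ** (k - 1) * np.exp(-t / theta1)
    g2 = t ** (k - 1) * np.exp(-t / theta2)
    g1 /= g1.max()
    g2 /= g2.max()
    kern = g1 - 0.5 * g2
    return kern / np.max(np.abs(kern))


def _unit_rms(x: np.ndarray) -> np.ndarray:
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def gen_eeg_epochs(cfg: SyntheticStudyConfig, fm: ForwardModelParams,
                   features: dict, scores: pd.DataFrame, seed: int = None,
                   repeats: int = None) -> dict:
    """Epoch pools keyed (participant, condition).

    epoch(c, t) = s(score) · (g_env·(kernel∗ENV) + g_ph·(kernel∗PH)) · w_c
    · response_scale  +  noise_scale · pink_noise(c, t), with w_c = 1 on the
    informative channels, 0 elsewhere, and s(score) = score / 100.  The
    response components are unit-RMS per sentence, so with the default
    response_scale = noise_scale each gain is a single-trial
    signal-to-noise ratio at score 100.  Noise is drawn independently of
    the gains, so two runs with equal seeds and different gains share the
    same noise field.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    repeats = cfg.repeats_per_sentence if repeats is None else repeats
    kern = response_kernel(cfg.rate, fm.kernel_latency, fm.kernel_width)

    responses = {}
    for sid, feats in features.items():
        env = feats["ENV"].values if isinstance(feats, dict) else feats.values
        ph = feats["PH"].values if isinstance(feats, dict) else None
        r = fm.tracking_gain_env * _unit_rms(
            sp_signal.fftconvolve(env, kern)[:EPOCH_N_SAMPLES])
        if ph is not None:
            r = r + fm.tracking_gain_ph * _unit_rms(
                sp_signal.fftconvolve(ph, kern)[:EPOCH_N_SAMPLES])
        responses[sid] = r

    w = np.zeros(N_CHANNELS)
    for lab in fm.informative_channels:
        w[MONTAGE_LABELS.index(lab)] = 1.0

    pools: dict = {}
    sids = sorted(features)
    for _, row in scores.iterrows():
        key = (row["participant"], row["condition"])
        s = float(row["score"]) / 100.0
        pool = []
        k = 0
        for sid in sids:
            clean = fm.response_scale * s * responses[sid][None, :] * w[:, None]
            for _rep in range(repeats):
                noise = _pink_noise((N_CHANNELS, EPOCH_N_SAMPLES), rng,
                                    fm.noise_exponent)
                data = clean + fm.noise_scale * noise
                pool.append(Epoch(data.astype(np.float32), sentence_id=sid,
                                  condition_id=row["condition"],
                                  participant_id=row["participant"],
                                  epoch_id=(row["participant"], row["condition"], k)))
                k += 1
        pools[key] = pool
    return pools


# ---------------------------------------------------------------------------
# Whole-study bundles


@dataclass
class SyntheticStudy:
    config: SyntheticStudyConfig
    sentences: dict  # sid -> (AudioWaveform, PhonemeOnsets)
    features: dict  # sid -> {kind -> FeatureSeries on the epoch time base}
    scores: pd.DataFrame
    pools: dict  # (participant, condition) -> [Epoch]
    labels: dict  # (participant, condition) -> ScoreLabel

    def features_of_kind(self, kind: str) -> dict:
        return {sid: feats[kind] for sid, feats in self.features.items()}


def make_study(cfg: SyntheticStudyConfig,
               fm: ForwardModelParams = ForwardModelParams(),
               psych: PsychometricParams = PsychometricParams(),
               repeats: int = None) -> SyntheticStudy:
    """Generate the full synthetic study deterministically from ``cfg.seed``."""
    sentences = {}
    features = {}
    for i in range(cfg.n_sentences):
        sid = f"sent{i:02d}"
        audio, onsets = gen_sentence(cfg, sid, seed=i)
        sentences[sid] = (audio, onsets)
        features[sid] = sentence_features(audio, onsets)
    scores = gen_behavioral_scores(cfg)
    pools = gen_eeg_epochs(cfg, fm, features, scores, repeats=repeats)
    labels = {
        (r["participant"], r["condition"]): ScoreLabel(r["score"])
        for _, r in scores.iterrows()
    }
    return SyntheticStudy(cfg, sentences, features, scores, pools, labels)


def scaled_study(seed: int = 0, n_subjects: int = 8, repeats: int = 20,
                 n_sentences: int = 2,
                 score_levels: tuple = (0.0, 25.0, 50.0, 75.0, 100.0),
                 fm: ForwardModelParams = ForwardModelParams()) -> SyntheticStudy:
    """Desk-scale validation profile: 5 fixed score levels, small pools.

    Each subject contributes one pool per score level (conditions are the
    levels themselves), so exactly ``len(score_levels)`` classes appear and
    class recovery can be measured on a single CPU.
    """
    cfg = SyntheticStudyConfig(n_subjects=n_subjects, n_sentences=n_sentences,
                               repeats_per_sentence=repeats, seed=seed,
                               conditions=tuple(f"lvl{int(s)}" for s in score_levels))
    sentences, features = {}, {}
    for i in range(cfg.n_sentences):
        sid = f"sent{i:02d}"
        audio, onsets = gen_sentence(cfg, sid, seed=i)
        sentences[sid] = (audio, onsets)
        features[sid] = sentence_features(audio, onsets)
    rows = [
        {"participant": f"S{s:03d}", "condition": f"lvl{int(lvl)}",
         "score": snap_to_grid(lvl)}
        for s in range(n_subjects) for lvl in score_levels
    ]
    scores = pd.DataFrame(rows)
    pools = gen_eeg_epochs(cfg, fm, features, scores, repeats=repeats)
    labels = {(r["participant"], r["condition"]): ScoreLabel(r["score"])
              for _, r in scores.iterrows()}
    return SyntheticStudy(cfg, sentences, features, scores, pools, labels)
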