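"""Training-set augmentation for 64 × 768 feature images.

Three perturbations, one chosen uniformly at random per augmented copy:

* additive Gaussian noise at a noise-to-signal RMS ratio of 0.6,
* a temporal cutout — a random contiguous 0.625 s window (160 columns at
  256 Hz, ~20 % of the 3 s epoch) replaced with Gaussian noise matched to
  the image's mean and standard deviation,
* sensor dropout — 12 random electrodes (~20 % of 64) zeroed.

Augmentation runs on the 64 × 768 matrices *before* rendering, so cutout
columns and dropout rows keep their time/channel meaning.  Originals are
retained; with the default expansion factor 10, 800 training images become
8,000.  Labels are never altered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .csep import FeatureImage
from .features import EEG_RATE

APPROACHES = ("gaussian_noise", "temporal_cutout", "sensor_dropout")
MAX_CUTOUT_S = 3.0


@dataclass(frozen=True)
class AugmentationConfig:
    noise_to_signal: float = 0.6
    cutout_duration: float = 0.625
    n_dropout_sensors: int = 12
    expansion_factor: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_to_signal < 0:
            raise ValueError("noise_to_signal must be >= 0")
        if not 0 < self.cutout_duration <= MAX_CUTOUT_S:
            raise ValueError(f"cutout_duration must be in (0, {MAX_CUTOUT_S}] s")
        if not 0 <= self.n_dropout_sensors <= 64:
            raise ValueError("n_dropout_sensors must be in [0, 64]")
        if self.expansion_factor < 1:
            raise ValueError("expansion_factor must be >= 1")


def _replace(img: FeatureImage, matrix: np.ndarray) -> FeatureImage:
    return FeatureImage(
        matrix, img.kind, label=img.label, participant_id=img.participant_id,
        condition_id=img.condition_id, source_epoch_ids=img.source_epoch_ids,
    )


def add_gaussian_noise(img: FeatureImage, nsr: float = 0.6, seed=0) -> FeatureImage:
    """Add zero-mean Gaussian noise rescaled so RMS(noise)/RMS(image) = nsr.

    The drawn noise field is rescaled exactly for each call, so the realized
    ratio equals ``nsr`` to machine precision.
    """
    if nsr < 0:
        raise ValueError("nsr must be >= 0")
    if nsr == 0:
        return _replace(img, img.matrix.copy())
    rms = np.sqrt(np.mean(np.square(img.matrix, dtype=np.float64)))
    if rms == 0:
        raise ValueError("noise-to-signal ratio undefined for an all-zero image")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    noise = rng.standard_normal(img.matrix.shape)
    noise *= nsr * rms / np.sqrt(np.mean(noise**2))
    return _replace(img, img.matrix + noise)


def temporal_cutout(
    img: FeatureImage, duration: float = 0.625, rate: float = EEG_RATE, seed=0
) -> FeatureImage:
    """Replace a random contiguous time window with matched Gaussian noise.

    The window spans ``round(duration * rate)`` columns across all 64 rows;
    fill noise matches the whole image's mean and standard deviation.
    """
    if duration == 0:
        return _replace(img, img.matrix.copy())
    if not 0 < duration <= MAX_CUTOUT_S:
        raise ValueError(f"cutout duration must be in (0, {MAX_CUTOUT_S}] s")
    n_cols = int(np.floor(duration * rate + 0.5))
    n_total = img.matrix.shape[1]
    if n_cols > n_total:
        raise ValueError("cutout window longer than the image")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    start = int(rng.integers(0, n_total - n_cols + 1))
    mat = img.matrix.copy()
    mu, sd = float(np.mean(mat)), float(np.std(mat))
    if sd == 0:
        sd = 1.0  # degenerate (constant) image: fill still carries noise
    mat[:, start : start + n_cols] = mu + sd * rng.standard_normal((mat.shape[0], n_cols))
    return _replace(img, mat)


def sensor_dropout(img: FeatureImage, n_sensors: int = 12, seed=0) -> FeatureImage:
    """Zero a random subset of exactly ``n_sensors`` distinct electrode rows."""
    if not 0 <= n_sensors <= img.matrix.shape[0]:
        raise ValueError(f"n_sensors must be in [0, {img.matrix.shape[0]}]")
    if n_sensors == 0:
        return _replace(img, img.matrix.copy())
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rows = rng.choice(img.matrix.shape[0], size=n_sensors, replace=False)
    mat = img.matrix.copy()
    mat[rows] = 0.0
    return _replace(img, mat)


def augment_dataset(train: list, cfg: AugmentationConfig = AugmentationConfig()) -> list:
    """Expand a training set by ``expansion_factor``.

    Originals are kept; each original contributes ``expansion_factor − 1``
    augmented copies, each produced by one of the three approaches chosen
    uniformly at random.  800 inputs at the default factor 10 yield 8,000.
    """
    if not train:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(cfg.seed)
    out = list(train)
    ops = {
        "gaussian_noise": lambda im: add_gaussian_noise(im, cfg.noise_to_signal, rng),
        "temporal_cutout": lambda im: temporal_cutout(im, cfg.cutout_duration, seed=rng),
        "sensor_dropout": lambda im: sensor_dropout(im, cfg.n_dropout_sensors, rng),
    }
    for img in train:
        for _ in range(cfg.expansion_factor - 1):
            approach = APPROACHES[rng.integers(0, len(APPROACHES))]
            out.append(ops[approach](img))
    return out
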