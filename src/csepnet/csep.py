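"""ERP and CSEP feature images for intelligibility decoding.

A **CSEP** (continuous speech-evoked potential) image holds, for each of the
64 channels, the Pearson correlation coefficient between the EEG epoch and a
stimulus feature (ENV, PH or PHENV) at every lag of a 768-lag grid spanning
−0.5 s to +2.496 s.  An **ERP** image is the plain average of epochs over
the same 64 × 768 geometry.  Bootstrap resampling draws intelligibility
classes uniformly so the training corpus is balanced across the 38 observed
score levels; epochs are split 80/20 before any averaging so no trial leaks
across the train/test boundary.  Images are min-max scaled and bilinearly
resized to 299 × 299 × 3 for the CNN.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from .features import EPOCH_N_SAMPLES, FeatureSeries
from .labels import ScoreLabel
from .montage import N_CHANNELS

#: Lag grid in samples: −128 (−0.5 s) .. 639 (+2.496 s), 768 lags, so CSEP
#: and ERP images share the 64 × 768 geometry.
DEFAULT_LAGS = np.arange(-128, 640)
DEFAULT_N_AVG = 80
MIN_OVERLAP = 8
IMAGE_SIZE = 299
IMAGE_KINDS = ("ERP", "ENV", "PH", "PHENV")


@dataclass(frozen=True)
class FeatureImage:
    """64 × 768 matrix (ERP: µV vs time; CSEP: correlation vs lag)."""

    matrix: np.ndarray
    kind: str
    label: ScoreLabel = None
    participant_id: str = ""
    condition_id: str = ""
    source_epoch_ids: tuple = ()

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.shape[0] != N_CHANNELS:
            raise ValueError(f"feature image must have {N_CHANNELS} rows")
        if self.kind not in IMAGE_KINDS:
            raise ValueError(f"kind must be one of {IMAGE_KINDS}")
        if self.kind != "ERP" and (m.min() < -1 - 1e-9 or m.max() > 1 + 1e-9):
            raise ValueError("CSEP entries must lie in [-1, 1]")
        object.__setattr__(self, "matrix", m)


@dataclass(frozen=True)
class RenderedImage:
    """size × size × 3 pixels in [0, 1] ready for the CNN."""

    pixels: np.ndarray
    kind: str
    label: ScoreLabel = None

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3 or p.shape[0] != p.shape[1]:
            raise ValueError("pixels must be size x size x 3")
        if p.min() < -1e-6 or p.max() > 1 + 1e-6:
            raise ValueError("pixel values must lie in [0, 1]")
        object.__setattr__(self, "pixels", p)


@dataclass
class DatasetSplit:
    train: list
    test: list
    split_fraction: float = 0.8
    seed: int = 0


# ---------------------------------------------------------------------------
# Lagged Pearson correlation


def xcorr_series(x, s, lags=DEFAULT_LAGS, min_overlap: int = MIN_OVERLAP) -> np.ndarray:
    """Pearson correlation between ``x(t)`` and ``s(t − lag)`` per lag.

    For each integer lag the coefficient is computed over the overlapping
    samples only.  Overlaps shorter than ``min_overlap`` samples, and
    zero-variance overlaps, yield a coefficient of 0.  Runs in O(N log N)
    via FFT cross-products plus cumulative-sum window moments; an O(N²)
    direct oracle exists in the test suite.
    """
    x = np.asarray(x, dtype=np.float64)
    out = _xcorr_rows(x[None, :] if x.ndim == 1 else x, np.asarray(s, np.float64),
                      np.asarray(lags), min_overlap)
    return out[0] if x.ndim == 1 else out


def _xcorr_rows(X: np.ndarray, s: np.ndarray, lags: np.ndarray, min_overlap: int) -> np.ndarray:
    from scipy.signal import fftconvolve

    C, N = X.shape
    if len(s) != N:
        raise ValueError(f"series length mismatch: {N} vs {len(s)}")
    if np.any(np.abs(lags) >= N):
        raise ValueError("lags must satisfy |lag| < series length")
    # Pearson is invariant to affine maps of either series; centring/scaling
    # globally conditions the windowed-moment arithmetic.
    Xc = X - X.mean(axis=1, keepdims=True)
    xs = Xc.std(axis=1)
    Xc = np.divide(Xc, xs[:, None], out=np.zeros_like(Xc), where=xs[:, None] > 0)
    sc = s - s.mean()
    ss_std = sc.std()
    if ss_std > 0:
        sc = sc / ss_std

    full = fftconvolve(Xc, sc[::-1][None, :], mode="full", axes=1)  # (C, 2N-1)
    sum_xy = full[:, (N - 1) + lags]

    cs_x = np.concatenate([np.zeros((C, 1)), np.cumsum(Xc, axis=1)], axis=1)
    cs_x2 = np.concatenate([np.zeros((C, 1)), np.cumsum(Xc**2, axis=1)], axis=1)
    cs_s = np.concatenate([[0.0], np.cumsum(sc)])
    cs_s2 = np.concatenate([[0.0], np.cumsum(sc**2)])

    x_lo = np.maximum(lags, 0)
    x_hi = N + np.minimum(lags, 0)
    s_lo = np.maximum(-lags, 0)
    s_hi = N - np.maximum(lags, 0)
    n = (x_hi - x_lo).astype(np.float64)

    sx = cs_x[:, x_hi] - cs_x[:, x_lo]
    sx2 = cs_x2[:, x_hi] - cs_x2[:, x_lo]
    ssum = (cs_s[s_hi] - cs_s[s_lo])[None, :]
    ss2 = (cs_s2[s_hi] - cs_s2[s_lo])[None, :]

    cov = n * sum_xy - sx * ssum
    var_x = n * sx2 - sx**2
    var_s = n * ss2 - ssum**2
    denom = np.sqrt(np.clip(var_x, 0, None) * np.clip(var_s, 0, None))
    valid = (n >= min_overlap) & (denom > n * 1e-12)
    r = np.zeros_like(cov)
    np.divide(cov, denom, out=r, where=valid)
    return np.clip(r, -1.0, 1.0)


# ---------------------------------------------------------------------------
# Feature-image construction


def _epoch_ids(epochs) -> tuple:
    return tuple(e.epoch_id for e in epochs)


def compute_erp(epochs: list, n_avg: int = DEFAULT_N_AVG, rng=None) -> FeatureImage:
    """Average ``n_avg`` epochs drawn with replacement into one ERP image.

    With ``n_avg=None`` the plain mean of the whole pool is returned
    (order-invariant, no resampling).
    """
    if not epochs:
        raise ValueError("cannot average an empty epoch pool")
    if n_avg is None:
        chosen = list(epochs)
    else:
        if n_avg < 1:
            raise ValueError("n_avg must be >= 1")
        rng = np.random.default_rng(0) if rng is None else rng
        chosen = [epochs[i] for i in rng.integers(0, len(epochs), size=n_avg)]
    mat = np.mean([e.data for e in chosen], axis=0)
    e0 = epochs[0]
    return FeatureImage(
        mat, "ERP", participant_id=e0.participant_id, condition_id=e0.condition_id,
        source_epoch_ids=_epoch_ids(chosen),
    )


def compute_csep(
    epochs: list,
    features: dict,
    n_avg: int = DEFAULT_N_AVG,
    lags: np.ndarray = DEFAULT_LAGS,
    rng=None,
) -> FeatureImage:
    """Average per-channel lagged correlations over resampled epochs.

    ``features`` maps sentence_id → a :class:`FeatureSeries` on the 768-sample
    epoch time base; each epoch is correlated with its own sentence's feature.
    """
    if not epochs:
        raise ValueError("cannot build a CSEP from an empty epoch pool")
    for e in epochs:
        if e.sentence_id not in features:
            raise KeyError(f"no stimulus feature for sentence {e.sentence_id!r}")
    feat0 = features[epochs[0].sentence_id]
    kind = feat0.kind if isinstance(feat0, FeatureSeries) else "ENV"
    if n_avg < 1:
        raise ValueError("n_avg must be >= 1")
    rng = np.random.default_rng(0) if rng is None else rng
    chosen = [epochs[i] for i in rng.integers(0, len(epochs), size=n_avg)]
    lags = np.asarray(lags)
    acc = np.zeros((N_CHANNELS, len(lags)))
    for e in chosen:
        f = features[e.sentence_id]
        vals = f.values if isinstance(f, FeatureSeries) else np.asarray(f)
        if len(vals) != EPOCH_N_SAMPLES:
            raise ValueError(
                f"feature for sentence {e.sentence_id!r} has {len(vals)} samples, "
                f"expected {EPOCH_N_SAMPLES} (epoch time base)"
            )
        acc += _xcorr_rows(e.data.astype(np.float64), vals, lags, MIN_OVERLAP)
    e0 = epochs[0]
    return FeatureImage(
        acc / len(chosen), kind, participant_id=e0.participant_id,
        condition_id=e0.condition_id, source_epoch_ids=_epoch_ids(chosen),
    )


# ---------------------------------------------------------------------------
# Bootstrap dataset generation


def bootstrap_dataset(
    epoch_pools: dict,
    labels: dict,
    n_train: int = 800,
    n_test: int = 200,
    kind: str = "ERP",
    seed: int = 0,
    features: dict = None,
    n_avg: int = DEFAULT_N_AVG,
    lags: np.ndarray = DEFAULT_LAGS,
    test_fraction: float = 0.2,
) -> DatasetSplit:
    """Class-balanced bootstrap of ERP/CSEP images with an 80/20 epoch split.

    ``epoch_pools`` maps (participant, condition) → list of epochs and
    ``labels`` maps the same keys → :class:`ScoreLabel`.  Each pool's epochs
    are first split 80/20; every train exemplar averages only train-side
    epochs and every test exemplar only test-side epochs.  Classes are drawn
    uniformly from the observed score levels, so exemplars are evenly
    distributed over intelligibility.
    """
    if kind not in IMAGE_KINDS:
        raise ValueError(f"kind must be one of {IMAGE_KINDS}")
    if kind != "ERP" and features is None:
        raise ValueError("CSEP kinds require a sentence_id -> feature map")
    if n_train <= 0 or n_test <= 0:
        raise ValueError("n_train and n_test must be positive")
    rng = np.random.default_rng(seed)

    by_class: dict = {}
    for key, lab in labels.items():
        if key not in epoch_pools:
            raise KeyError(f"label for {key} has no epoch pool")
        by_class.setdefault(lab.score, []).append(key)
    classes = sorted(by_class)
    missing = [c for c in classes if not by_class[c]]
    if missing:
        raise ValueError(f"classes with no epoch pool: {missing}")

    sides: dict = {}
    for key, pool in epoch_pools.items():
        if len(pool) < 2:
            raise ValueError(f"pool {key} needs >= 2 epochs for a disjoint split")
        perm = rng.permutation(len(pool))
        n_test_ep = max(1, int(round(test_fraction * len(pool))))
        sides[key] = {
            "test": [pool[i] for i in perm[:n_test_ep]],
            "train": [pool[i] for i in perm[n_test_ep:]],
        }

    def make_exemplar(side: str) -> FeatureImage:
        score = classes[rng.integers(0, len(classes))]
        pool_keys = by_class[score]
        key = pool_keys[rng.integers(0, len(pool_keys))]
        epochs = sides[key][side]
        if kind == "ERP":
            img = compute_erp(epochs, n_avg=n_avg, rng=rng)
        else:
            img = compute_csep(epochs, features, n_avg=n_avg, lags=lags, rng=rng)
        return FeatureImage(
            img.matrix, kind, label=ScoreLabel(score),
            participant_id=img.participant_id, condition_id=img.condition_id,
            source_epoch_ids=img.source_epoch_ids,
        )

    train = [make_exemplar("train") for _ in range(n_train)]
    test = [make_exemplar("test") for _ in range(n_test)]
    return DatasetSplit(train, test, 1 - test_fraction, seed)


# ---------------------------------------------------------------------------
# Rendering


def render_image(img: FeatureImage, size: int = IMAGE_SIZE) -> RenderedImage:
    """Min-max scale, bilinearly resize to size × size, replicate to 3 channels.

    A constant matrix renders as all-0.5.  Non-constant inputs are
    renormalized after interpolation so the rendered min is exactly 0 and
    the max exactly 1.
    """
    m = np.asarray(img.matrix, dtype=np.float64)
    if not np.all(np.isfinite(m)):
        raise ValueError("feature image contains non-finite values")
    lo, hi = m.min(), m.max()
    if hi - lo < 1e-300:
        plane = np.full((size, size), 0.5)
    else:
        norm = (m - lo) / (hi - lo)
        plane = _sk_resize(norm, (size, size), order=1, mode="edge",
                           anti_aliasing=False, preserve_range=True)
        lo2, hi2 = plane.min(), plane.max()
        plane = (plane - lo2) / (hi2 - lo2) if hi2 > lo2 else np.full_like(plane, 0.5)
    pixels = np.repeat(plane[:, :, None], 3, axis=2).astype(np.float32)
    return RenderedImage(pixels, img.kind, img.label)


def render_dataset(images: list, size: int = IMAGE_SIZE):
    """Stack rendered images into (n, size, size, 3) X and score vector y."""
    X = np.stack([render_image(im, size).pixels for im in images])
    y = np.array([im.label.score if im.label else np.nan for im in images])
    return X, y


# ---------------------------------------------------------------------------
# Serialization: compressed numeric container + JSON manifest


def save_images(path, images: list, seed: int = None, config: dict = None) -> None:
    manifest = {
        "n_images": len(images),
        "kinds": [im.kind for im in images],
        "scores": [None if im.label is None else im.label.score for im in images],
        "participants": [im.participant_id for im in images],
        "conditions": [im.condition_id for im in images],
        "seed": seed,
        "config": config or {},
    }
    np.savez_compressed(
        path,
        matrices=np.stack([im.matrix for im in images]).astype(np.float32),
        manifest=np.frombuffer(json.dumps(manifest).encode(), dtype=np.uint8),
    )


def load_images(path) -> list:
    with np.load(path) as z:
        manifest = json.loads(bytes(z["manifest"]).decode())
        mats = z["matrices"].astype(np.float64)
    images = []
    for i in range(manifest["n_images"]):
        score = manifest["scores"][i]
        images.append(
            FeatureImage(
                mats[i], manifest["kinds"][i],
                label=None if score is None else ScoreLabel(score),
                participant_id=manifest["participants"][i],
                condition_id=manifest["conditions"][i],
            )
        )
    return images
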