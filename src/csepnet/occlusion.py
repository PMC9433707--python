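"""Occlusion-sensitivity attribution over the 64-electrode montage.

A trained model's decision is probed by sliding a small occluding patch
(default 5 × 5 pixels, stride 5) over the rendered input and recording the
drop in the true-class softmax probability.  The resulting sensitivity grid
is aggregated back onto electrodes: each image row band (≈ image_height/64
pixel rows per channel) collects the grid cells it overlaps, weighted by
fractional overlap, and the per-channel scores are ranked to name the most
informative electrodes.  A topographic head map renders the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .labels import score_to_class
from .montage import Montage, load_montage

DEFAULT_MASK = 5
DEFAULT_STRIDE = 5
#: Occluder fill value: the rendered-image midpoint (a constant image value).
DEFAULT_BASELINE = 0.5
DEFAULT_TOP_K = 10


@dataclass(frozen=True)
class OcclusionMap:
    """Probability-drop grid for one image and one evaluated class."""

    grid: np.ndarray
    mask_size: int
    stride: int
    class_index: int
    image_shape: tuple

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=np.float64)
        if not np.all(np.isfinite(g)):
            raise ValueError("occlusion grid contains non-finite values")
        h = -(-self.image_shape[0] // self.stride)
        w = -(-self.image_shape[1] // self.stride)
        if g.shape != (h, w):
            raise ValueError(f"grid shape {g.shape} inconsistent with "
                             f"ceil(image/stride) = {(h, w)}")
        object.__setattr__(self, "grid", g)


@dataclass(frozen=True)
class ChannelSensitivity:
    scores: np.ndarray
    channel_labels: tuple
    band_widths: np.ndarray = None

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=np.float64)
        if len(s) != len(self.channel_labels):
            raise ValueError("one score per channel label required")
        object.__setattr__(self, "scores", s)


def _predict_proba_batch(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba_grid"):
        return model.predict_proba_grid(X)
    return model.predict_proba(X, 64)


def occlusion_map(model, image, class_index: int, mask_size: int = DEFAULT_MASK,
                  stride: int = DEFAULT_STRIDE, baseline: float = DEFAULT_BASELINE,
                  batch_size: int = 64) -> OcclusionMap:
    """Sensitivity = p_true(original) − p_true(occluded) per grid position.

    ``image`` is (H, W, 3) in [0, 1]; ``class_index`` is the evaluated class
    (0..37; use :func:`csepnet.labels.score_to_class` to convert a score).
    A 299 × 299 input with mask 5 / stride 5 yields a 60 × 60 grid.
    """
    if mask_size <= 0 or stride <= 0:
        raise ValueError("mask_size and stride must be positive")
    pixels = np.asarray(getattr(image, "pixels", image), dtype=np.float32)
    H, W, _ = pixels.shape
    cls = int(class_index)
    gh, gw = -(-H // stride), -(-W // stride)

    p0 = float(_predict_proba_batch(model, pixels[None])[0, cls])
    grid = np.empty((gh, gw))
    positions = [(r, c) for r in range(gh) for c in range(gw)]
    for i in range(0, len(positions), batch_size):
        chunk = positions[i : i + batch_size]
        batch = np.repeat(pixels[None], len(chunk), axis=0)
        for j, (r, c) in enumerate(chunk):
            batch[j, r * stride : r * stride + mask_size,
                  c * stride : c * stride + mask_size, :] = baseline
        probs = _predict_proba_batch(model, batch)[:, cls]
        for j, (r, c) in enumerate(chunk):
            grid[r, c] = p0 - float(probs[j])
    return OcclusionMap(grid, mask_size, stride, cls, (H, W))


def _band_weights(image_height: int, n_grid_rows: int, stride: int,
                  n_channels: int) -> np.ndarray:
    """(n_channels, n_grid_rows) fractional overlap of channel bands with
    grid rows; columns sum to 1, so band widths sum to the grid-row count."""
    w = np.zeros((n_channels, n_grid_rows))
    band = image_height / n_channels
    for r in range(n_grid_rows):
        lo = r * stride
        hi = min(lo + stride, image_height)
        height = hi - lo
        c0 = int(lo // band)
        c1 = min(int(np.ceil(hi / band)), n_channels)
        for c in range(c0, c1):
            overlap = min(hi, (c + 1) * band) - max(lo, c * band)
            if overlap > 0:
                w[c, r] = overlap / height
    return w


def map_to_channels(omap: OcclusionMap, montage: Montage = None,
                    signed: bool = False) -> ChannelSensitivity:
    """Aggregate a sensitivity grid to one score per electrode.

    Grid values are averaged over all lag columns (absolute values by
    default) and distributed over the 64 channel row bands by fractional
    overlap.  The per-channel band widths partition the grid rows exactly.
    """
    montage = montage or load_montage()
    n_ch = len(montage.labels)
    grid = omap.grid if signed else np.abs(omap.grid)
    row_means = grid.mean(axis=1)
    w = _band_weights(omap.image_shape[0], omap.grid.shape[0], omap.stride, n_ch)
    widths = w.sum(axis=1)
    scores = np.divide(w @ row_means, widths, out=np.zeros(n_ch), where=widths > 0)
    return ChannelSensitivity(scores, montage.labels, widths)


def topk_channels(cs: ChannelSensitivity, k: int = DEFAULT_TOP_K) -> list:
    """Labels of the k largest scores, descending; ties keep montage order."""
    if not 1 <= k <= len(cs.channel_labels):
        raise ValueError(f"k must be in [1, {len(cs.channel_labels)}]")
    order = np.argsort(-cs.scores, kind="stable")
    return [cs.channel_labels[i] for i in order[:k]]


def render_topomap(cs: ChannelSensitivity, montage: Montage = None,
                   path=None, cmap: str = "Reds"):
    """Interpolated head-plane map of channel sensitivity, written to file.

    Values are min-max scaled; dark to bright marks low to high contribution.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.interpolate import griddata

    montage = montage or load_montage()
    pos = montage.positions
    vals = cs.scores.astype(np.float64)
    rng_ = vals.max() - vals.min()
    scaled = (vals - vals.min()) / rng_ if rng_ > 0 else np.full_like(vals, 0.5)

    radius = 1.2
    gx, gy = np.meshgrid(np.linspace(-radius, radius, 201),
                         np.linspace(-radius, radius, 201))
    gz = griddata(pos, scaled, (gx, gy), method="cubic")
    outside = np.hypot(gx, gy) > radius
    gz = np.where(outside, np.nan, gz)

    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(gz, extent=(-radius, radius, -radius, radius), origin="lower",
                   cmap=cmap, vmin=0, vmax=1)
    ax.add_patch(plt.Circle((0, 0), 1.0, fill=False, color="k", lw=1.5))
    ax.scatter(pos[:, 0], pos[:, 1], s=8, c="k", zorder=3)
    ax.set_xlim(-radius, radius)
    ax.set_ylim(-radius, radius)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.colorbar(im, ax=ax, shrink=0.8, label="relative sensitivity")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return path
    return fig


def mean_occlusion_channels(model, X, y, montage: Montage = None,
                            mask_size: int = DEFAULT_MASK,
                            stride: int = DEFAULT_STRIDE,
                            max_images: int = None,
                            correct_only: bool = True) -> ChannelSensitivity:
    """Channel sensitivity averaged over (correctly classified) test images."""
    montage = montage or load_montage()
    y = np.asarray(y, dtype=np.float64)
    if correct_only:
        pred = model.predict(X)
        keep = np.flatnonzero(pred == y)
    else:
        keep = np.arange(len(y))
    if len(keep) == 0:
        raise ValueError("no (correctly classified) images to attribute")
    if max_images is not None:
        keep = keep[:max_images]
    total = np.zeros(len(montage.labels))
    for i in keep:
        omap = occlusion_map(model, X[i], score_to_class(y[i]), mask_size, stride)
        total += map_to_channels(omap, montage).scores
    return ChannelSensitivity(total / len(keep), montage.labels)
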