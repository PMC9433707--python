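"""The packaged 64-channel montage (extended 10-20, Biosemi-64 layout).

Two-dimensional head-plane coordinates are shipped as a CSV asset
(label, x, y), derived from the standard Biosemi-64 electrode positions via
azimuthal projection with the equator (ear-level ring) at radius 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np


@dataclass(frozen=True)
class Montage:
    labels: tuple
    positions: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.float64)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("montage labels must be unique")
        if pos.shape != (len(self.labels), 2):
            raise ValueError("positions must be (n_labels, 2)")
        if np.any(np.hypot(pos[:, 0], pos[:, 1]) > 1.2):
            raise ValueError("montage coordinates must lie within 1.2 of the origin")
        object.__setattr__(self, "positions", pos)

    def index(self, label: str) -> int:
        return self.labels.index(label)


def load_montage() -> Montage:
    """Load the packaged 64-channel montage CSV."""
    text = resources.files("csepnet.data").joinpath("biosemi64.csv").read_text()
    labels, xs, ys = [], [], []
    for line in text.splitlines()[1:]:
        lab, x, y = line.split(",")
        labels.append(lab)
        xs.append(float(x))
        ys.append(float(y))
    return Montage(tuple(labels), np.column_stack([xs, ys]))


_MONTAGE = load_montage()
MONTAGE_LABELS: tuple = _MONTAGE.labels
N_CHANNELS: int = len(MONTAGE_LABELS)
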