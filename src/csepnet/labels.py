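"""Behavioral speech-intelligibility score grid and class labels.

Scores from the sentence recognition test lie on a 0–100 grid with a step
of 2.5 (41 nominal levels).  Three levels — 30.0, 37.5 and 40.0 — were never
produced by any listener, leaving 38 observed classes.  Classes are indexed
by the rank of the score in the sorted 38-element label set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Full nominal grid: 0, 2.5, ..., 100 (41 levels).
FULL_GRID: tuple[float, ...] = tuple(np.round(np.arange(0, 100.1, 2.5), 1))

#: Score levels absent from the behavioral data.
EXCLUDED_SCORES: frozenset[float] = frozenset({30.0, 37.5, 40.0})

#: The 38 observed score levels, sorted ascending.
SCORE_GRID: tuple[float, ...] = tuple(
    s for s in FULL_GRID if s not in EXCLUDED_SCORES
)

N_CLASSES: int = len(SCORE_GRID)  # 38

_SCORE_TO_CLASS = {s: i for i, s in enumerate(SCORE_GRID)}


def score_to_class(score: float) -> int:
    """Map an observed score to its class index (0..37)."""
    s = round(float(score), 1)
    try:
        return _SCORE_TO_CLASS[s]
    except KeyError:
        raise ValueError(
            f"score {score} is not on the observed 2.5-step grid "
            f"(excluded levels: {sorted(EXCLUDED_SCORES)})"
        ) from None


def class_to_score(index: int) -> float:
    """Map a class index back to its score level."""
    if not 0 <= index < N_CLASSES:
        raise ValueError(f"class index {index} outside 0..{N_CLASSES - 1}")
    return SCORE_GRID[index]


def snap_to_grid(value: float) -> float:
    """Snap an arbitrary 0–100 value to the nearest *observed* grid level.

    Values landing on an excluded level (30.0, 37.5, 40.0) move to the
    nearest allowed neighbour; exact midpoints resolve downward.
    """
    v = min(max(float(value), 0.0), 100.0)
    grid = np.asarray(SCORE_GRID)
    return float(grid[np.argmin(np.abs(grid - v))])


@dataclass(frozen=True)
class ScoreLabel:
    """A behavioral score together with its 38-class index."""

    score: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "score", round(float(self.score), 1))
        score_to_class(self.score)  # validates

    @property
    def class_index(self) -> int:
        return score_to_class(self.score)
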