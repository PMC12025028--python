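"""Granular label system for pouring gestures.

The task has four primary gesture categories — pouring left, pouring right,
pouring front, and holding the bottle — and each pouring direction is
executed at one of four wrist angles (22.5, 45, 67.5 or 90 degrees).
Granular computing treats these as nested granules:

* ``granular1`` — 13 classes: every (direction, angle) pair plus hold.
* ``granular2`` — 7 classes: angles pooled into a shallow group
  {22.5, 45} and a steep group {67.5, 90} per direction, plus hold.
* ``coarse`` — 4 classes: the primary categories themselves.

A coarsening function maps any finer granule back onto its primary
category, so a model trained on fine subclasses can always be scored at
the coarse level.

Fine integer ids follow the confusion-matrix numbering used for this
protocol: 1-4 left pouring, 6-9 right pouring, 11-14 front pouring,
5 hold (14 is the largest id; 10 is an alias of 5 because the hold trial
is recorded twice per repetition).  Within each direction block ids are
ordered by ascending angle (1 = left 22.5 deg, ..., 4 = left 90 deg).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "Direction",
    "Level",
    "GestureLabel",
    "N_CLASSES",
    "ANGLES",
    "all_labels",
    "granulate",
    "coarsen",
    "coarsen_probabilities",
    "membership_matrix",
    "label_map_frame",
]


class Direction(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    FRONT = "front"
    HOLD = "hold"


class Level(str, Enum):
    """Granularity levels, ordered fine to coarse."""

    GRANULAR1 = "granular1"  # 13 classes
    GRANULAR2 = "granular2"  # 7 classes
    COARSE = "coarse"  # 4 classes


ANGLES: tuple[float, ...] = (22.5, 45.0, 67.5, 90.0)

N_CLASSES: dict[Level, int] = {
    Level.GRANULAR1: 13,
    Level.GRANULAR2: 7,
    Level.COARSE: 4,
}

#: ordering rank, finer = smaller
_FINENESS = {Level.GRANULAR1: 0, Level.GRANULAR2: 1, Level.COARSE: 2}

#: coarse class order is (left, right, front, hold)
_COARSE_ORDER = (Direction.LEFT, Direction.RIGHT, Direction.FRONT, Direction.HOLD)

#: fine-id base per direction block (ascending angle within the block)
_FINE_BASE = {Direction.LEFT: 1, Direction.RIGHT: 6, Direction.FRONT: 11}

HOLD_FINE_ID = 5
HOLD_FINE_ALIAS = 10


@dataclass(frozen=True)
class GestureLabel:
    """A pouring gesture: direction plus execution angle (absent for hold)."""

    direction: Direction
    angle: float | None = None

    def __post_init__(self) -> None:
        direction = Direction(self.direction)
        object.__setattr__(self, "direction", direction)
        if direction is Direction.HOLD:
            if self.angle is not None:
                raise ValueError("hold carries no angle")
        else:
            if self.angle not in ANGLES:
                raise ValueError(
                    f"angle must be one of {ANGLES}, got {self.angle!r}"
                )
            object.__setattr__(self, "angle", float(self.angle))

    @property
    def fine_id(self) -> int:
        """Confusion-matrix id: 1-4 left, 5 hold, 6-9 right, 11-14 front."""
        if self.direction is Direction.HOLD:
            return HOLD_FINE_ID
        return _FINE_BASE[self.direction] + ANGLES.index(self.angle)

    @classmethod
    def from_fine_id(cls, fine_id: int) -> "GestureLabel":
        fine_id = int(fine_id)
        if fine_id in (HOLD_FINE_ID, HOLD_FINE_ALIAS):
            return cls(Direction.HOLD)
        for direction, base in _FINE_BASE.items():
            if base <= fine_id <= base + 3:
                return cls(direction, ANGLES[fine_id - base])
        raise ValueError(f"fine id must be in 1..14, got {fine_id}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.direction is Direction.HOLD:
            return "hold"
        return f"{self.direction.value}@{self.angle:g}"


def all_labels() -> list[GestureLabel]:
    """The 13 distinct gesture labels, in granular1 class-index order."""
    labels = [
        GestureLabel(d, a)
        for d in (Direction.LEFT, Direction.RIGHT, Direction.FRONT)
        for a in ANGLES
    ]
    labels.append(GestureLabel(Direction.HOLD))
    return labels


def granulate(label: GestureLabel, level: Level | str) -> int:
    """Class index of *label* at *level*, contiguous in ``0..K-1``.

    Index order is direction blocks (left, right, front) with ascending
    angle inside each block, hold last — matching the coarse order
    (left, right, front, hold).
    """
    level = Level(level)
    d = label.direction
    if d is Direction.HOLD:
        return N_CLASSES[level] - 1
    block = _COARSE_ORDER.index(d)
    if level is Level.COARSE:
        return block
    angle_rank = ANGLES.index(label.angle)
    if level is Level.GRANULAR1:
        return block * 4 + angle_rank
    # granular2: shallow group {22.5, 45} -> 0, steep group {67.5, 90} -> 1
    return block * 2 + (0 if angle_rank < 2 else 1)


def _check_levels(from_level: Level | str, to_level: Level | str) -> tuple[Level, Level]:
    from_level, to_level = Level(from_level), Level(to_level)
    if _FINENESS[from_level] > _FINENESS[to_level]:
        raise ValueError(
            f"cannot refine {from_level.value} to {to_level.value}: "
            "coarsening is not invertible"
        )
    return from_level, to_level


def coarsen(class_index: int, from_level: Level | str, to_level: Level | str) -> int:
    """Map a class index at *from_level* onto the granule containing it at
    *to_level* (a coarser or equal level)."""
    from_level, to_level = _check_levels(from_level, to_level)
    k = N_CLASSES[from_level]
    class_index = int(class_index)
    if not 0 <= class_index < k:
        raise ValueError(f"class index {class_index} out of range for {from_level.value}")
    if from_level is to_level:
        return class_index
    if class_index == k - 1:  # hold granule is a singleton at every level
        return N_CLASSES[to_level] - 1
    per_block_from = 4 if from_level is Level.GRANULAR1 else 2
    block, within = divmod(class_index, per_block_from)
    if to_level is Level.COARSE:
        return block
    # granular1 -> granular2
    return block * 2 + (0 if within < 2 else 1)


def membership_matrix(from_level: Level | str, to_level: Level | str) -> np.ndarray:
    """0/1 granule-membership matrix ``G`` of shape (K_to, K_from) with
    ``G[i, j] = 1`` iff fine class j coarsens to class i."""
    from_level, to_level = _check_levels(from_level, to_level)
    g = np.zeros((N_CLASSES[to_level], N_CLASSES[from_level]), dtype=np.int64)
    for j in range(N_CLASSES[from_level]):
        g[coarsen(j, from_level, to_level), j] = 1
    return g


def coarsen_probabilities(
    p: np.ndarray, from_level: Level | str, to_level: Level | str
) -> np.ndarray:
    """Aggregate class probabilities over granules by summing member mass.

    *p* may be a single probability vector or a matrix of row vectors.
    Each row must sum to 1 within 1e-6.
    """
    from_level, to_level = _check_levels(from_level, to_level)
    p = np.asarray(p, dtype=float)
    squeeze = p.ndim == 1
    rows = np.atleast_2d(p)
    if rows.shape[1] != N_CLASSES[from_level]:
        raise ValueError(
            f"expected {N_CLASSES[from_level]} classes for {from_level.value}, "
            f"got {rows.shape[1]}"
        )
    if np.any(rows < -1e-9) or not np.allclose(rows.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("rows must be probability vectors summing to 1")
    g = membership_matrix(from_level, to_level).astype(float)
    out = rows @ g.T
    return out[0] if squeeze else out


def label_map_frame() -> pd.DataFrame:
    """Tabular export of the full label map (one row per fine id 1..14)."""
    rows = []
    for fid in range(1, 15):
        lab = GestureLabel.from_fine_id(fid)
        rows.append(
            {
                "fine_id": fid,
                "direction": lab.direction.value,
                "angle": "" if lab.angle is None else lab.angle,
                "granular1_idx": granulate(lab, Level.GRANULAR1),
                "granular2_idx": granulate(lab, Level.GRANULAR2),
                "coarse_idx": granulate(lab, Level.COARSE),
            }
        )
    return pd.DataFrame(rows)
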