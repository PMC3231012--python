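"""Replicate-channel averaging and odor-pattern normalization.

The Cyranose 320 carries 32 carbon-black composite channels in 8 replicate
groups of 4; averaging replicates yields one stable response per sensor type.
Normalizing the resulting pattern removes concentration magnitude: under the
homogeneity assumption (response proportional to concentration) the
normalized pattern of a pure compound is the same at every concentration,
which is what lets a classifier group mixtures by *which* components are
present rather than how much.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["ReplicateMap", "average_replicates", "normalize_pattern", "NORMALIZATION_MODES"]

NORMALIZATION_MODES = ("l2", "sum", "max")


@dataclass(frozen=True)
class ReplicateMap:
    """Disjoint groups of raw channel indices (0-based) to average."""

    groups: tuple[tuple[int, ...], ...]

    def __init__(self, groups: Sequence[Sequence[int]]):
        groups = tuple(tuple(int(i) for i in g) for g in groups)
        if any(len(g) == 0 for g in groups):
            raise ValueError("replicate groups must be non-empty")
        flat = [i for g in groups for i in g]
        if len(flat) != len(set(flat)):
            raise ValueError("replicate groups must be disjoint")
        if any(i < 0 for i in flat):
            raise ValueError("channel indices must be non-negative")
        object.__setattr__(self, "groups", groups)

    @classmethod
    def consecutive(cls, n_channels: int, group_size: int) -> "ReplicateMap":
        """n_channels split into consecutive groups of group_size (default e-nose layout)."""
        if n_channels % group_size:
            raise ValueError("n_channels must be a multiple of group_size")
        return cls(
            [
                tuple(range(g * group_size, (g + 1) * group_size))
                for g in range(n_channels // group_size)
            ]
        )

    @property
    def m(self) -> int:
        return len(self.groups)


def average_replicates(raw: np.ndarray, rep_map: ReplicateMap) -> np.ndarray:
    """Arithmetic mean of raw channels within each replicate group."""
    raw = np.asarray(raw, dtype=float)
    top = max(i for g in rep_map.groups for i in g)
    if top >= raw.shape[-1]:
        raise IndexError(
            f"replicate map references channel {top} but raw has {raw.shape[-1]}"
        )
    return np.array([raw[..., list(g)].mean(axis=-1) for g in rep_map.groups]).T \
        if raw.ndim > 1 else np.array([raw[list(g)].mean() for g in rep_map.groups])


def normalize_pattern(x: np.ndarray, mode: str = "l2") -> np.ndarray:
    """Scale a response pattern to unit size, preserving its direction.

    mode "l2": unit Euclidean norm; "sum": entries sum to 1 (non-negative
    input required); "max": maximum entry 1.  An all-zero vector has no
    direction and is rejected.
    """
    x = np.asarray(x, dtype=float)
    if mode not in NORMALIZATION_MODES:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if not np.any(x != 0):
        raise ValueError("cannot normalize an all-zero pattern")
    if mode == "l2":
        scale = float(np.linalg.norm(x))
    elif mode == "sum":
        if np.any(x < 0):
            raise ValueError("sum normalization requires non-negative entries")
        scale = float(x.sum())
    else:  # max
        scale = float(x.max())
        if scale <= 0:
            raise ValueError("max normalization requires a positive maximum")
    return x / scale
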