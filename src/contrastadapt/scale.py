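"""Logarithmic contrast scales backing the matching slider.

Two variants are used.  The replication slider spans 0.01-1.0 in 1000
geometric steps with a zero entry prepended at position 0 (so the match
grating can be switched off entirely).  The classroom-exercise slider spans
0.05-1.0 in 1000 geometric steps with no zero, and is cut at a random
position on every trial: the value at the cut becomes position 0 and the
values before the cut wrap to the right-hand end, so observers cannot reuse
remembered slider positions across trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ContrastScale",
    "log_spaced",
    "build_replication_scale",
    "build_exercise_scale",
    "rotate",
    "contrast_at",
    "nearest_position",
]


def log_spaced(lo: float, hi: float, n: int) -> np.ndarray:
    """Geometric sequence of ``n`` values from ``lo`` to ``hi`` inclusive.

    v_i = lo * (hi/lo)**(i/(n-1)); endpoints are exact.
    """
    if not lo > 0:
        raise ValueError("lo must be > 0")
    if not hi > lo:
        raise ValueError("hi must be > lo")
    if n < 2:
        raise ValueError("n must be >= 2")
    return np.geomspace(lo, hi, n)


@dataclass(frozen=True)
class ContrastScale:
    """Ordered list of selectable contrast values, possibly rotated.

    ``cut_index`` is the cumulative rotation offset: the value currently at
    position 0 originally sat at position ``cut_index`` of the unrotated
    scale.  ``has_zero`` scales (replication variant) are never rotated.
    """

    values: np.ndarray
    lo: float
    hi: float
    n_steps: int
    has_zero: bool = False
    cut_index: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1:
            raise ValueError("values must be 1-D")
        if len(v) != self.n_steps + (1 if self.has_zero else 0):
            raise ValueError("length inconsistent with n_steps/has_zero")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError("contrast values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def min_positive(self) -> float:
        pos = self.values[self.values > 0]
        return float(pos.min())


def build_replication_scale() -> ContrastScale:
    """1000 log-spaced contrasts on [0.01, 1.0] with zero prepended (1001 entries)."""
    vals = np.concatenate([[0.0], log_spaced(0.01, 1.0, 1000)])
    return ContrastScale(values=vals, lo=0.01, hi=1.0, n_steps=1000, has_zero=True)


def build_exercise_scale() -> ContrastScale:
    """1000 log-spaced contrasts on [0.05, 1.0], no zero entry."""
    vals = log_spaced(0.05, 1.0, 1000)
    return ContrastScale(values=vals, lo=0.05, hi=1.0, n_steps=1000, has_zero=False)


def rotate(scale: ContrastScale, cut: int) -> ContrastScale:
    """Cut the scale at ``cut`` and wrap: values[cut:] ++ values[:cut].

    The contrast formerly at position ``cut`` becomes position 0.  Only
    zero-free (exercise) scales may be rotated.
    """
    if scale.has_zero:
        raise ValueError("a scale with a zero entry cannot be rotated")
    n = len(scale)
    if not 0 <= cut < n:
        raise ValueError(f"cut must be in [0, {n}), got {cut}")
    vals = np.concatenate([scale.values[cut:], scale.values[:cut]])
    return replace(scale, values=vals, cut_index=(scale.cut_index + cut) % n)


def contrast_at(scale: ContrastScale, position: int) -> float:
    """Contrast value paired with a slider position."""
    n = len(scale)
    if not 0 <= position < n:
        raise ValueError(f"position must be in [0, {n}), got {position}")
    return float(scale.values[position])


def nearest_position(scale: ContrastScale, target: float) -> int:
    """Slider position whose contrast is log-nearest to ``target``.

    The scale is geometric, so distance is measured between logarithms.
    A target of exactly 0 maps to the zero entry when one exists; targets
    at or below the smallest positive value map to that value's position.
    """
    if not 0.0 <= target <= 1.0:
        raise ValueError("target must be in [0, 1]")
    if target == 0.0 and scale.has_zero:
        return int(np.flatnonzero(scale.values == 0.0)[0])
    t = max(target, scale.min_positive)
    vals = scale.values
    with np.errstate(divide="ignore"):
        dist = np.abs(np.log(vals) - np.log(t))  # zero entry -> inf distance
    return int(np.argmin(dist))
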