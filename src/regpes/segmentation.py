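"""Stationary-point detection and segmentation of a discrete energy profile.

REG analysis operates on *segments*: contiguous stretches of the potential
energy surface between two subsequent stationary points (reactant, transition
state, product, ...).  Stationary points are detected on the discrete total
energy series itself -- the analysis only ever selects among the computed
geometries, never interpolated ones.

Exact plateaus (zero finite difference) are merged into the surrounding
trend rather than spawning degenerate segments; when a plateau sits at a
local extremum its first index is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = ["Trend", "Segment", "find_stationary_points", "split_segments"]


class Trend(str, Enum):
    RISING = "rising"
    FALLING = "falling"


@dataclass(frozen=True)
class Segment:
    """Inclusive index range [start_index, end_index] into the point axis.

    Consecutive segments share exactly their boundary index, and the union
    of all segments covers the whole profile with no gaps.
    """

    start_index: int
    end_index: int
    classification: Trend

    def __post_init__(self) -> None:
        if self.end_index - self.start_index < 1:
            raise ValueError("a segment spans at least two points")
        if self.start_index < 0:
            raise ValueError("segment indices must be non-negative")

    @property
    def n_points(self) -> int:
        return self.end_index - self.start_index + 1

    @property
    def slice(self) -> slice:
        return slice(self.start_index, self.end_index + 1)

    def as_dict(self) -> dict:
        return {
            "start_index": self.start_index,
            "end_index": self.end_index,
            "classification": self.classification.value,
        }


def find_stationary_points(e_total) -> list[int]:
    """Indices of the discrete stationary points of an energy series.

    A stationary point is an index where the sign of successive finite
    differences changes; the first and last indices are always included.
    Zero differences inherit the surrounding trend (plateaus do not spawn
    segments) and the first index of a tied extremum is kept.
    """
    e = np.asarray(e_total, dtype=float)
    if e.ndim != 1 or e.size < 2:
        raise ValueError("energy series must be 1-D with at least 2 points")
    m = e.size
    # compress exact plateaus into runs; run starts keep the first tied index
    run_starts = [0]
    for j in range(1, m):
        if e[j] != e[run_starts[-1]]:
            run_starts.append(j)
    values = e[run_starts]
    diffs = np.sign(np.diff(values))  # all nonzero by construction
    stationary = {0, m - 1}
    for k in range(1, len(diffs)):
        if diffs[k] != diffs[k - 1]:
            stationary.add(run_starts[k])
    return sorted(stationary)


def split_segments(dataset) -> list[Segment]:
    """Split a dataset (or bare energy series) into trend-classified segments.

    Accepts a :class:`~regpes.energy_data.Dataset` or any 1-D array of total
    energies.  Each segment runs between two consecutive stationary points
    and is classified rising/falling by comparing its endpoint energies
    (an exactly flat segment is reported as rising).
    """
    e = np.asarray(getattr(dataset, "e_total", dataset), dtype=float)
    points = find_stationary_points(e)
    segments = []
    for a, b in zip(points[:-1], points[1:]):
        trend = Trend.FALLING if e[b] < e[a] else Trend.RISING
        segments.append(Segment(start_index=a, end_index=b, classification=trend))
    return segments
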