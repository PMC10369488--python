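"""Relative energy gradient (REG) coefficients per segment.

For every partitioned term E_i the REG coefficient is the slope of an
ordinary least-squares fit of the mean-translated term series against the
mean-translated total energy over the points of one segment:

    m_i = cov(E_i, E_tot) / var(E_tot)

After translation the intercept is identically zero, so the covariance
ratio *is* the OLS slope.  The coefficient depends only on the energy
gradients, never on the control-coordinate values themselves.  A Pearson
correlation R_i accompanies every slope as the linearity diagnostic; terms
with |R| below a threshold are flagged as discarded (but always retained in
the output so either reporting convention can be reproduced).

For an exact additive decomposition the slopes obey the completeness sum
rule sum_i m_i = 1 on every segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy_data import Dataset, TermLabel
from .segmentation import Segment, Trend, split_segments

__all__ = [
    "MIN_SEGMENT_POINTS",
    "DEFAULT_R_THRESHOLD",
    "DegenerateSegmentError",
    "RegEntry",
    "RegResult",
    "center",
    "reg_value",
    "pearson",
    "analyze_segment",
    "analyze",
]

#: 2-point segments always give |R| = 1, which is meaningless; require 3.
MIN_SEGMENT_POINTS = 3

#: default Pearson cutoff below which a term is flagged as discarded
DEFAULT_R_THRESHOLD = 0.7


class DegenerateSegmentError(ValueError):
    """Raised when a segment is too short or has zero variance to regress on."""


def _segment_slice(segment) -> slice:
    if isinstance(segment, Segment):
        return segment.slice
    start, end = segment  # (start_index, end_index) inclusive
    return slice(int(start), int(end) + 1)


def center(series, segment) -> np.ndarray:
    """Translate a series over its own mean across the segment's points."""
    window = np.asarray(series, dtype=float)[_segment_slice(segment)]
    if window.size < MIN_SEGMENT_POINTS:
        raise DegenerateSegmentError(
            f"segment has {window.size} point(s); at least "
            f"{MIN_SEGMENT_POINTS} are required for regression"
        )
    return window - window.mean()


def reg_value(term_series, total_series, segment) -> float:
    """OLS slope of the mean-translated term against the total energy."""
    y = center(term_series, segment)
    x = center(total_series, segment)
    sxx = float(x @ x)
    if sxx == 0.0:
        raise DegenerateSegmentError("total energy has zero variance on this segment")
    return float(y @ x) / sxx


def pearson(term_series, total_series, segment) -> float:
    """Product-moment correlation of a term with the total energy."""
    y = center(term_series, segment)
    x = center(total_series, segment)
    sxx = float(x @ x)
    syy = float(y @ y)
    if sxx == 0.0 or syy == 0.0:
        raise DegenerateSegmentError("zero variance on this segment")
    r = float(x @ y) / np.sqrt(sxx * syy)
    return min(1.0, max(-1.0, r))


@dataclass(frozen=True)
class RegEntry:
    """One term's (REG, Pearson) pair within a segment.

    ``rank`` is the 1-based position among retained (non-discarded) entries
    ordered from most positive to most negative REG; ``None`` for discarded
    entries.  A constant term has slope 0 and an undefined correlation; it
    is reported with pearson 0 and flagged discarded.
    """

    label: TermLabel
    reg: float
    pearson: float
    segment_id: int
    discarded: bool
    rank: int | None


@dataclass
class RegResult:
    """REG analysis of one segment: every term's entry plus sum diagnostics.

    ``sum_of_reg`` is computed over ALL terms (it equals 1 for an exact
    decomposition); ``sum_of_reg_retained`` restricts the sum to entries
    surviving the |R| threshold, so both reporting conventions are visible.
    """

    segment: Segment
    segment_id: int
    r_threshold: float
    entries: list[RegEntry] = field(default_factory=list)
    sum_of_reg: float = float("nan")
    sum_of_reg_retained: float = float("nan")
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None

    def as_dict(self) -> dict:
        return {
            "segment": self.segment.as_dict(),
            "segment_id": self.segment_id,
            "r_threshold": self.r_threshold,
            "sum_of_reg": self.sum_of_reg,
            "sum_of_reg_retained": self.sum_of_reg_retained,
            "error": self.error,
            "entries": [
                {
                    "rank": entry.rank,
                    "label": str(entry.label),
                    "reg": entry.reg,
                    "pearson": entry.pearson,
                    "discarded": entry.discarded,
                }
                for entry in self.entries
            ],
        }


def analyze_segment(
    dataset: Dataset,
    segment: Segment,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    segment_id: int = 0,
) -> RegResult:
    """Compute (REG, Pearson) for every term of ``dataset`` on one segment.

    Entries are sorted by REG from most positive to most negative, ties
    broken by canonical label order.  Entries with |R| < ``r_threshold``
    are flagged discarded but kept in the output.
    """
    if not (0.0 <= r_threshold < 1.0):
        raise ValueError("r_threshold must satisfy 0 <= r_threshold < 1")
    x = center(dataset.e_total, segment)
    sxx = float(x @ x)
    if sxx == 0.0:
        raise DegenerateSegmentError("total energy has zero variance on this segment")
    sl = _segment_slice(segment)
    raw: list[tuple[TermLabel, float, float, bool]] = []
    for label in dataset.sorted_labels():
        window = dataset.terms[label][sl]
        y = window - window.mean()
        reg = float(y @ x) / sxx
        syy = float(y @ y)
        if syy == 0.0:
            # constant term: zero slope, correlation undefined -> discard
            raw.append((label, reg, 0.0, True))
            continue
        r = float(min(1.0, max(-1.0, float(x @ y) / np.sqrt(sxx * syy))))
        raw.append((label, reg, r, bool(abs(r) < r_threshold)))

    raw.sort(key=lambda item: (-item[1], item[0]))
    entries: list[RegEntry] = []
    rank = 0
    for label, reg, r, discarded in raw:
        if discarded:
            entry_rank = None
        else:
            rank += 1
            entry_rank = rank
        entries.append(
            RegEntry(
                label=label,
                reg=reg,
                pearson=r,
                segment_id=segment_id,
                discarded=discarded,
                rank=entry_rank,
            )
        )
    return RegResult(
        segment=segment,
        segment_id=segment_id,
        r_threshold=r_threshold,
        entries=entries,
        sum_of_reg=float(sum(item[1] for item in raw)),
        sum_of_reg_retained=float(sum(item[1] for item in raw if not item[3])),
    )


def analyze(dataset: Dataset, r_threshold: float = DEFAULT_R_THRESHOLD) -> list[RegResult]:
    """Segment the dataset and run :func:`analyze_segment` on every segment.

    A degenerate segment (fewer than 3 points, or zero total-energy
    variance) produces a result entry carrying the error message; analysis
    of the remaining segments proceeds.
    """
    results = []
    for i, segment in enumerate(split_segments(dataset)):
        try:
            results.append(analyze_segment(dataset, segment, r_threshold, segment_id=i))
        except DegenerateSegmentError as exc:
            results.append(
                RegResult(
                    segment=segment,
                    segment_id=i,
                    r_threshold=r_threshold,
                    error=str(exc),
                )
            )
    return results
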