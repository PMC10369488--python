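"""Atom-subset ("lite" system) selection and truncation assessment.

Two routes to a reduced system are supported:

* *biased* selection -- a sphere of chosen radius around a reference atom
  (typically the reactive center) picks the chemically relevant atoms, and
  the partitioned-term table is filtered down to terms whose atoms all lie
  inside the subset while the full-system totals are kept;
* *unbiased* assessment -- a systematically truncated system is judged by
  comparing its energy profile against the full-system profile through
  three unity-convergence metrics: the OLS slope m of the mean-translated
  lite-vs-full regression, the coefficient of determination R^2 of that
  fit, and the ratio of endpoint energy differences dE_lite/dE_full
  (the activation-energy ratio when the segment runs reactant -> transition
  state).  The closer all three are to one, the more faithful the subset.

Candidates are ranked by the largest deviation of the triple from unity
(an L-infinity aggregation), so a profile that matches in shape but not in
gradient (m ~ 1, R^2 ~ 1, dE ratio well below 1) never ranks best.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy_data import Dataset, Geometry, _atom_label
from .rdp_select import Polyline

__all__ = [
    "TruncationMetrics",
    "TruncationAssessment",
    "sphere_select",
    "filter_terms",
    "truncation_metrics",
    "assess_truncations",
]


def sphere_select(geometry: Geometry, center_label: str, radius: float) -> set[str]:
    """Labels of all atoms within ``radius`` (A) of the center atom.

    Membership uses the closed ball (distance <= radius), so atoms exactly
    on the boundary are included; the center atom always is.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    center = geometry.position_of(center_label)
    distances = np.linalg.norm(geometry.positions() - center, axis=1)
    return {label for label, d in zip(geometry.labels, distances) if d <= radius}


def filter_terms(dataset: Dataset, atom_subset) -> Dataset:
    """Keep exactly the terms whose every atom lies in ``atom_subset``.

    The control coordinate and the full-system total energies are kept
    unchanged -- under the biased protocol the lite terms are still taken
    from the full-system wave-function, so the totals remain the reference.
    The result therefore no longer satisfies the recovery-error or REG sum
    rules unless the subset is the full atom set.
    """
    subset = {_atom_label(a) for a in atom_subset}
    if not subset:
        raise ValueError("atom subset must be non-empty")
    kept = {
        label: series
        for label, series in dataset.terms.items()
        if all(atom in subset for atom in label.atoms)
    }
    return Dataset(
        s=dataset.s.copy(),
        e_total=dataset.e_total.copy(),
        terms=kept,
        unit=dataset.unit,
        source=f"{dataset.source} | subset of {len(subset)} atoms",
    )


@dataclass(frozen=True)
class TruncationMetrics:
    """Unity-convergence triple (m, R^2, dE ratio) for one lite candidate."""

    name: str
    n_atoms: int | None
    m: float
    r2: float
    de_ratio: float

    @property
    def max_unity_deviation(self) -> float:
        return max(abs(self.m - 1.0), abs(self.r2 - 1.0), abs(self.de_ratio - 1.0))

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "n_atoms": self.n_atoms,
            "m": self.m,
            "r2": self.r2,
            "de_ratio": self.de_ratio,
            "max_unity_deviation": self.max_unity_deviation,
        }


def _profile_arrays(profile) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(profile, Polyline):
        return profile.x, profile.y
    x, y = profile
    return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


def truncation_metrics(
    full_profile,
    lite_profile,
    segment=None,
    name: str = "",
    n_atoms: int | None = None,
) -> TruncationMetrics:
    """Compare a lite-system profile against the full-system profile.

    Both profiles must live on the identical control-coordinate grid.  The
    assessed range defaults to the whole profile; passing a
    :class:`~regpes.segmentation.Segment` (or ``(start, end)`` pair)
    restricts all three metrics to that index range.
    """
    xf, yf = _profile_arrays(full_profile)
    xl, yl = _profile_arrays(lite_profile)
    if xf.shape != xl.shape or not np.allclose(xf, xl, rtol=1e-12, atol=0.0):
        raise ValueError("full and lite profiles must share an identical grid")
    if segment is None:
        start, end = 0, xf.size - 1
    else:
        start = getattr(segment, "start_index", None)
        if start is None:
            start, end = int(segment[0]), int(segment[1])
        else:
            end = segment.end_index
    full = yf[start : end + 1]
    lite = yl[start : end + 1]
    if full.size < 3:
        raise ValueError("assessed segment needs at least 3 points")
    f = full - full.mean()
    l = lite - lite.mean()
    sff = float(f @ f)
    if sff == 0.0:
        raise ValueError("full profile has zero variance on the assessed segment")
    m = float(l @ f) / sff
    sll = float(l @ l)
    r2 = 0.0 if sll == 0.0 else float(l @ f) ** 2 / (sff * sll)
    de_full = float(full[-1] - full[0])
    if de_full == 0.0:
        raise ValueError("full-profile endpoint difference is zero; dE ratio undefined")
    de_ratio = float(lite[-1] - lite[0]) / de_full
    return TruncationMetrics(name=name, n_atoms=n_atoms, m=m, r2=min(1.0, r2),
                             de_ratio=de_ratio)


@dataclass
class TruncationAssessment:
    """Ranked truncation candidates plus any per-candidate failures."""

    ranked: list[TruncationMetrics]
    failures: list[tuple[str, str]]


def assess_truncations(full_profile, candidates, segment=None) -> TruncationAssessment:
    """Rank lite candidates by their worst deviation of (m, R^2, dE) from 1.

    ``candidates`` is an iterable of ``(name, lite_profile)`` or
    ``(name, lite_profile, n_atoms)`` tuples.  A candidate that fails
    validation is reported in ``failures`` and the rest proceed.
    """
    ranked: list[TruncationMetrics] = []
    failures: list[tuple[str, str]] = []
    for item in candidates:
        name, lite = item[0], item[1]
        n_atoms = item[2] if len(item) > 2 else None
        try:
            ranked.append(
                truncation_metrics(full_profile, lite, segment=segment,
                                   name=name, n_atoms=n_atoms)
            )
        except ValueError as exc:
            failures.append((name, str(exc)))
    ranked.sort(key=lambda metrics: (metrics.max_unity_deviation, metrics.name))
    return TruncationAssessment(ranked=ranked, failures=failures)
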