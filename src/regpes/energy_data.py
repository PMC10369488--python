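"""Domain types and I/O for additively partitioned energy decompositions.

An additive energy decomposition (interacting quantum atoms and related
schemes) expresses the total energy of a molecular system at each point of a
one-dimensional control coordinate *s* as a sum of per-atom self energies
(``intra``), classical electrostatic pair interactions (``cl``), and
exchange--correlation pair interactions (``xc``).  This module provides

* :class:`TermLabel` -- the canonical identity of one partitioned term,
* :class:`Dataset` -- the full collection of term series plus the total
  wave-function energy along the coordinate,
* :class:`Geometry` and XYZ I/O for atom-subset selection,
* the recovery-error diagnostic (how well the partitioned terms sum back to
  the total energy), and
* term-counting arithmetic for a system of *n* atoms.

Energies are tagged with a unit; kJ/mol is the default and hartree is
accepted with the CODATA conversion factor.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HARTREE_TO_KJ_PER_MOL",
    "TermKind",
    "TermLabel",
    "canonical_label",
    "Dataset",
    "Atom",
    "Geometry",
    "RecoveryReport",
    "read_dataset",
    "write_dataset",
    "read_xyz",
    "write_xyz",
    "recovery_error",
    "term_count",
]

#: kJ/mol per hartree (CODATA).
HARTREE_TO_KJ_PER_MOL = 2625.4996394799

KJ_PER_MOL = "kJ/mol"
HARTREE = "hartree"

#: conversion factor of each supported unit to kJ/mol
_UNIT_TO_KJ = {KJ_PER_MOL: 1.0, HARTREE: HARTREE_TO_KJ_PER_MOL}


class TermKind(str, Enum):
    """Kind of a partitioned energy term."""

    INTRA = "intra"  #: intra-atomic (self) energy of one topological atom
    CL = "cl"  #: classical electrostatic interatomic energy
    XC = "xc"  #: exchange--correlation interatomic energy


# lowercase element symbol (or generic letters) followed by a positive index
_ATOM_LABEL_RE = re.compile(r"^[a-z]+[1-9][0-9]*$")


def _atom_label(raw: str) -> str:
    """Normalize an atom label: case-insensitive input, stored lowercase."""
    label = str(raw).strip().lower()
    if not _ATOM_LABEL_RE.match(label):
        raise ValueError(
            f"malformed atom label {raw!r}: expected letters followed by a "
            "positive index, e.g. 'o66' or 'h100'"
        )
    return label


@dataclass(frozen=True, order=True)
class TermLabel:
    """Canonical identity of one partitioned energy term.

    ``intra`` terms carry exactly one atom label; ``cl``/``xc`` terms carry
    an unordered pair of two distinct atoms, stored in lexicographic order so
    that V(a, b) and V(b, a) map to the same label.  Instances are immutable
    and totally ordered (by kind, then atoms), which fixes tie-breaks in
    ranked output.
    """

    kind: TermKind
    atoms: tuple[str, ...]

    def __post_init__(self) -> None:
        n_expected = 1 if self.kind is TermKind.INTRA else 2
        if len(self.atoms) != n_expected:
            raise ValueError(
                f"{self.kind.value} term requires {n_expected} atom(s), "
                f"got {self.atoms!r}"
            )

    def __str__(self) -> str:
        return f"{self.kind.value}({','.join(self.atoms)})"


def canonical_label(kind: TermKind | str, atom_a: str, atom_b: str | None = None) -> TermLabel:
    """Build the canonical :class:`TermLabel` for a term.

    Pair labels are symmetric: the order of ``atom_a``/``atom_b`` never
    affects the result.  Raises :class:`ValueError` on malformed labels, on a
    pair of identical atoms, or when the atom count does not match the kind.
    """
    kind = TermKind(kind)
    a = _atom_label(atom_a)
    if kind is TermKind.INTRA:
        if atom_b is not None:
            raise ValueError("intra terms take a single atom, got a second one")
        return TermLabel(kind, (a,))
    if atom_b is None:
        raise ValueError(f"{kind.value} terms require two atoms")
    b = _atom_label(atom_b)
    if a == b:
        raise ValueError(
            f"pair term {kind.value} requires two distinct atoms, got {a!r} twice"
        )
    return TermLabel(kind, (a, b) if a < b else (b, a))


@dataclass(eq=False)
class Dataset:
    """All energy series of one system along its control coordinate.

    Parameters
    ----------
    s:
        Control-coordinate values, strictly increasing, length M >= 2.
    e_total:
        Total (wave-function) energy at each point, same length as ``s``.
    terms:
        Mapping from :class:`TermLabel` to its M-point energy series.
    unit:
        Energy unit tag, ``"kJ/mol"`` (default) or ``"hartree"``.
    source:
        Free-text provenance description.
    """

    s: np.ndarray
    e_total: np.ndarray
    terms: dict[TermLabel, np.ndarray]
    unit: str = KJ_PER_MOL
    source: str = ""

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.e_total = np.asarray(self.e_total, dtype=float)
        if self.s.ndim != 1 or self.s.size < 2:
            raise ValueError("control coordinate must be 1-D with at least 2 points")
        if self.e_total.shape != self.s.shape:
            raise ValueError(
                f"e_total has shape {self.e_total.shape}, expected {self.s.shape}"
            )
        diffs = np.diff(self.s)
        if not np.all(diffs > 0):
            raise ValueError("control coordinate must be strictly increasing")
        if self.unit not in _UNIT_TO_KJ:
            raise ValueError(
                f"unknown unit {self.unit!r}; supported: {sorted(_UNIT_TO_KJ)}"
            )
        validated: dict[TermLabel, np.ndarray] = {}
        for label, series in self.terms.items():
            if not isinstance(label, TermLabel):
                raise TypeError(f"term keys must be TermLabel, got {label!r}")
            arr = np.asarray(series, dtype=float)
            if arr.shape != self.s.shape:
                raise ValueError(
                    f"term {label} has {arr.size} point(s), expected {self.s.size}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite energy in term {label}")
            validated[label] = arr
        self.terms = validated
        if not (np.all(np.isfinite(self.s)) and np.all(np.isfinite(self.e_total))):
            raise ValueError("non-finite values in s or e_total")

    @property
    def n_points(self) -> int:
        return int(self.s.size)

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def sorted_labels(self) -> list[TermLabel]:
        """Term labels in canonical (deterministic) order."""
        return sorted(self.terms)

    def term_matrix(self) -> np.ndarray:
        """Stack all term series into an (n_terms, M) matrix, labels sorted."""
        if not self.terms:
            return np.empty((0, self.n_points))
        return np.vstack([self.terms[label] for label in self.sorted_labels()])

    def in_unit(self, unit: str) -> "Dataset":
        """Return a copy converted to ``unit`` (kJ/mol or hartree)."""
        if unit not in _UNIT_TO_KJ:
            raise ValueError(f"unknown unit {unit!r}")
        factor = _UNIT_TO_KJ[self.unit] / _UNIT_TO_KJ[unit]
        return Dataset(
            s=self.s.copy(),
            e_total=self.e_total * factor,
            terms={label: v * factor for label, v in self.terms.items()},
            unit=unit,
            source=self.source,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return (
            np.array_equal(self.s, other.s)
            and np.array_equal(self.e_total, other.e_total)
            and self.unit == other.unit
            and set(self.terms) == set(other.terms)
            and all(np.array_equal(v, other.terms[k]) for k, v in self.terms.items())
        )


# ---------------------------------------------------------------------------
# long-format term-table I/O
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["point_index", "s", "kind", "atom_a", "atom_b", "energy"]
_TOTAL_KIND = "total"


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write a :class:`Dataset` as a long-format delimited table.

    One row per (label, point): columns ``point_index, s, kind, atom_a,
    atom_b, energy``.  Total-energy rows use kind ``total`` with empty atom
    columns.  Floats are written with 17 significant digits so the
    read/write round trip is exact, and row order is deterministic (total
    rows first, then terms in canonical order).
    """
    rows: list[tuple] = []
    for j in range(dataset.n_points):
        rows.append((j, dataset.s[j], _TOTAL_KIND, "", "", dataset.e_total[j]))
    for label in dataset.sorted_labels():
        series = dataset.terms[label]
        atom_a = label.atoms[0]
        atom_b = label.atoms[1] if len(label.atoms) == 2 else ""
        for j in range(dataset.n_points):
            rows.append((j, dataset.s[j], label.kind.value, atom_a, atom_b, series[j]))
    frame = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    frame.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")


def read_dataset(path: str | Path, unit: str = KJ_PER_MOL) -> Dataset:
    """Read a long-format term table into a validated :class:`Dataset`.

    The file must be UTF-8 delimited text (comma or tab) with a header row
    and columns ``point_index, s, kind, atom_a, atom_b, energy``.  Every
    label must be present at every point: missing combinations, duplicates
    (including a pair listed in both atom orders), ragged series,
    non-monotonic ``s`` and unknown kind tokens are all errors -- nothing is
    silently zero-filled.
    """
    frame = pd.read_csv(
        path,
        sep=None,
        engine="python",
        keep_default_na=False,
        na_values=[],
        dtype=str,
    )
    missing = [c for c in _TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"term table {path} is missing column(s) {missing}")

    try:
        point_index = frame["point_index"].astype(int).to_numpy()
        s_col = frame["s"].astype(float).to_numpy()
        energy = frame["energy"].astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"non-numeric value in term table {path}: {exc}") from None

    points = np.unique(point_index)
    n_points = points.size
    if not np.array_equal(points, np.arange(n_points)):
        raise ValueError("point_index values must cover 0..M-1 contiguously")

    # the control coordinate must be consistent across all rows of a point
    s = np.full(n_points, np.nan)
    for j, sj in zip(point_index, s_col):
        if np.isnan(s[j]):
            s[j] = sj
        elif s[j] != sj:
            raise ValueError(f"inconsistent s values at point_index {j}")

    e_total = np.full(n_points, np.nan)
    seen: dict[tuple[TermLabel | None, int], bool] = {}
    series: dict[TermLabel, np.ndarray] = {}
    for row, (j, kind_token) in enumerate(zip(point_index, frame["kind"])):
        atom_a = frame["atom_a"].iat[row].strip()
        atom_b = frame["atom_b"].iat[row].strip()
        kind_token = kind_token.strip()
        if kind_token == _TOTAL_KIND:
            if atom_a or atom_b:
                raise ValueError(f"total row at point {j} must have empty atom columns")
            key: tuple[TermLabel | None, int] = (None, j)
            if key in seen:
                raise ValueError(f"duplicate total-energy entry at point {j}")
            seen[key] = True
            e_total[j] = energy[row]
            continue
        try:
            label = canonical_label(kind_token, atom_a, atom_b or None)
        except ValueError as exc:
            raise ValueError(f"invalid term row {row} in {path}: {exc}") from None
        key = (label, j)
        if key in seen:
            raise ValueError(f"duplicate entry for {label} at point {j}")
        seen[key] = True
        if label not in series:
            series[label] = np.full(n_points, np.nan)
        series[label][j] = energy[row]

    if np.isnan(e_total).any():
        bad = int(np.flatnonzero(np.isnan(e_total))[0])
        raise ValueError(f"missing total-energy entry at point {bad}")
    for label, values in series.items():
        if np.isnan(values).any():
            bad = int(np.flatnonzero(np.isnan(values))[0])
            raise ValueError(f"term {label} is missing at point {bad}")

    return Dataset(s=s, e_total=e_total, terms=series, unit=unit, source=str(path))


# ---------------------------------------------------------------------------
# geometries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Atom:
    """One atom record: unique label, element symbol, Cartesian position (A)."""

    label: str
    element: str
    position: tuple[float, float, float]


@dataclass(eq=False)
class Geometry:
    """Ordered atom records; 1-based file order defines default label indices."""

    atoms: tuple[Atom, ...]

    def __post_init__(self) -> None:
        self.atoms = tuple(self.atoms)
        labels = [a.label for a in self.atoms]
        if len(set(labels)) != len(labels):
            raise ValueError("atom labels must be unique")
        for atom in self.atoms:
            if not all(math.isfinite(c) for c in atom.position):
                raise ValueError(f"non-finite coordinate for atom {atom.label}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def labels(self) -> list[str]:
        return [a.label for a in self.atoms]

    def positions(self) -> np.ndarray:
        """Coordinates as an (n_atoms, 3) float array."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def position_of(self, label: str) -> np.ndarray:
        label = _atom_label(label)
        for atom in self.atoms:
            if atom.label == label:
                return np.asarray(atom.position, dtype=float)
        raise KeyError(f"no atom labelled {label!r} in geometry")


def read_xyz(path: str | Path, label_column: bool = False) -> Geometry:
    """Read a standard XYZ file (count line, comment line, element x y z rows).

    Default atom labels are the lowercase element symbol plus the 1-based
    file position (``o1``, ``h2``, ...).  With ``label_column=True`` a fifth
    column supplies explicit labels instead.

    The parser keeps full float64 precision of the coordinates, so a
    write/read round trip is exact.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"empty XYZ file {path}")
    try:
        count = int(lines[0].strip())
    except ValueError:
        raise ValueError(f"first line of {path} must be the atom count") from None
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) != count:
        raise ValueError(
            f"XYZ header declares {count} atoms but {len(body)} atom rows found"
        )
    atoms = []
    for i, line in enumerate(body):
        fields = line.split()
        n_expected = 5 if label_column else 4
        if len(fields) < n_expected:
            raise ValueError(f"atom row {i + 1} of {path} has too few columns")
        element = fields[0]
        try:
            xyz = tuple(float(v) for v in fields[1:4])
        except ValueError:
            raise ValueError(f"non-numeric coordinate on atom row {i + 1} of {path}") from None
        label = fields[4] if label_column else f"{element.lower()}{i + 1}"
        atoms.append(Atom(label=_atom_label(label), element=element, position=xyz))
    return Geometry(atoms=tuple(atoms))


def write_xyz(geometry: Geometry, path: str | Path, comment: str = "") -> None:
    """Write a geometry as standard XYZ with 17-significant-digit coordinates."""
    lines = [str(geometry.n_atoms), comment]
    for atom in geometry.atoms:
        x, y, z = atom.position
        lines.append(f"{atom.element} {x:.17g} {y:.17g} {z:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class RecoveryReport:
    """Per-point recovery residuals and their aggregates.

    ``residuals[j] = sum_i E_i(s_j) - E_tot(s_j)``.  The RMSE of the
    residuals measures the numerical quality of the partitioning; for an
    exact additive decomposition it is zero.  ``relative_percent`` expresses
    the RMSE as a percentage of the mean absolute total energy.
    """

    residuals: np.ndarray
    rmse: float
    max_abs: float
    relative_percent: float

    def as_dict(self) -> dict:
        return {
            "residuals": [float(r) for r in self.residuals],
            "rmse": float(self.rmse),
            "max_abs": float(self.max_abs),
            "relative_percent": float(self.relative_percent),
        }


def recovery_error(dataset: Dataset) -> RecoveryReport:
    """Compute the recovery error of a partitioned dataset.

    Requires at least one term.  A constant residual indicates a systematic
    shift, which leaves energy gradients (and hence REG values) untouched.
    """
    if dataset.n_terms == 0:
        raise ValueError("recovery error needs at least one partitioned term")
    residuals = dataset.term_matrix().sum(axis=0) - dataset.e_total
    rmse = float(np.sqrt(np.mean(residuals**2)))
    scale = float(np.mean(np.abs(dataset.e_total)))
    relative = 100.0 * rmse / scale if scale > 0 else math.nan
    return RecoveryReport(
        residuals=residuals,
        rmse=rmse,
        max_abs=float(np.max(np.abs(residuals))),
        relative_percent=relative,
    )


def term_count(n_atoms: int) -> dict[str, int]:
    """Number of partitioned terms for a system of ``n_atoms`` atoms.

    ``n`` intra-atomic terms plus ``n(n-1)/2`` pairs each for the classical
    and exchange--correlation interactions, for ``n**2`` terms in total.
    """
    n = int(n_atoms)
    if n != n_atoms or n < 1:
        raise ValueError("n_atoms must be a positive integer")
    n_pairs = n * (n - 1) // 2
    return {"n_intra": n, "n_cl": n_pairs, "n_xc": n_pairs, "n_total": n * n}
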