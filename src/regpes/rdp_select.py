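"""Ramer--Douglas--Peucker geometry selection for energy profiles.

The RDP algorithm simplifies a polyline by recursively keeping the point
farthest from the chord between the current endpoints whenever its
perpendicular distance exceeds a tolerance epsilon.  Because epsilon lives
in mixed (coordinate, energy) units with no physical meaning of its own,
the selection here follows an epsilon *scan*: epsilon is swept from 0 to
the largest chord deviation, each simplification is converted into an RMSE
in energy units by linearly interpolating the retained points back onto the
original abscissae, and the user chooses a set by an RMSE tolerance
instead of by epsilon directly.

By default the abscissa is rescaled to [0, 1] before distances are
measured, so that the perpendicular distance is dominated by the energy
axis and the scan behaves identically regardless of the units of the
control coordinate (disable with ``normalize_x=False``).

The RMSE averages the vertical deviations over *all* original points
(retained points contribute zero); this convention is recorded here and an
eliminated-points-only average is available through :func:`rmse_for`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Polyline",
    "ScanRow",
    "SelectionResult",
    "read_profile",
    "write_profile",
    "perpendicular_distance",
    "rdp",
    "interpolate_on_retained",
    "rmse_for",
    "epsilon_max",
    "epsilon_scan",
    "select_points",
]

DEFAULT_STEP = 0.01


@dataclass(eq=False)
class Polyline:
    """Ordered (x, y) pairs with strictly increasing, finite x."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.x.size < 2 or self.x.shape != self.y.shape:
            raise ValueError("polyline needs matching 1-D x and y with >= 2 points")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("polyline coordinates must be finite")
        if not np.all(np.diff(self.x) > 0):
            raise ValueError("polyline x must be strictly increasing")

    @property
    def n_points(self) -> int:
        return int(self.x.size)


def read_profile(path: str | Path) -> Polyline:
    """Read a two-column (coordinate, energy) delimited text file.

    A header row is optional; comma and tab delimiters are accepted.
    """
    first = Path(path).open().readline()
    token = first.replace(",", " ").replace("\t", " ").split()[0]
    try:
        float(token)
        header = None
    except ValueError:
        header = 0
    # parse through str -> float64 to keep correctly-rounded full precision
    frame = pd.read_csv(path, sep=None, engine="python", header=header, dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"profile {path} must have two columns")
    return Polyline(x=frame.iloc[:, 0].astype(float).to_numpy(),
                    y=frame.iloc[:, 1].astype(float).to_numpy())


def write_profile(polyline: Polyline, path: str | Path) -> None:
    frame = pd.DataFrame({"s": polyline.x, "energy": polyline.y})
    frame.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")


def _as_xy(polyline) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(polyline, Polyline):
        return polyline.x, polyline.y
    x, y = polyline
    return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


def perpendicular_distance(point, seg_a, seg_b) -> float:
    """Distance from ``point`` to the infinite line through ``seg_a``/``seg_b``.

    Degenerates to the Euclidean point distance when the two line points
    coincide.
    """
    px, py = float(point[0]), float(point[1])
    ax, ay = float(seg_a[0]), float(seg_a[1])
    bx, by = float(seg_b[0]), float(seg_b[1])
    dx, dy = bx - ax, by - ay
    length = float(np.hypot(dx, dy))
    if length == 0.0:
        return float(np.hypot(px - ax, py - ay))
    return abs(dx * (py - ay) - dy * (px - ax)) / length


def _chord_distances(x: np.ndarray, y: np.ndarray, i: int, j: int) -> np.ndarray:
    """Distances of interior points i+1..j-1 to the line through points i, j."""
    dx, dy = x[j] - x[i], y[j] - y[i]
    length = float(np.hypot(dx, dy))
    xs, ys = x[i + 1 : j], y[i + 1 : j]
    if length == 0.0:
        return np.hypot(xs - x[i], ys - y[i])
    return np.abs(dx * (ys - y[i]) - dy * (xs - x[i])) / length


def rdp(polyline, epsilon: float) -> list[int]:
    """Classic recursive RDP simplification; returns retained indices.

    A farthest point is kept only if its distance is *strictly* larger than
    ``epsilon``; ties are broken toward the lowest index, and the first and
    last points are always retained.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    x, y = _as_xy(polyline)
    n = x.size
    keep = np.zeros(n, dtype=bool)
    keep[0] = keep[-1] = True
    _simplify(x, y, 0, n - 1, float(epsilon), keep)
    return [int(i) for i in np.flatnonzero(keep)]


def _simplify(x, y, i, j, epsilon, keep) -> None:
    # recursion depth is bounded by the point count; profiles are short
    if j <= i + 1:
        return
    distances = _chord_distances(x, y, i, j)
    k_rel = int(np.argmax(distances))  # argmax keeps the first (lowest) index
    if distances[k_rel] > epsilon:
        k = i + 1 + k_rel
        keep[k] = True
        _simplify(x, y, i, k, epsilon, keep)
        _simplify(x, y, k, j, epsilon, keep)


def interpolate_on_retained(polyline, retained) -> np.ndarray:
    """Piecewise-linear interpolation of the retained points at every x.

    Eliminated points are projected vertically onto the simplified
    polyline; retained abscissae reproduce their own y exactly.
    """
    x, y = _as_xy(polyline)
    retained = sorted(int(i) for i in retained)
    if not retained or retained[0] != 0 or retained[-1] != x.size - 1:
        raise ValueError("retained indices must include the first and last point")
    return np.interp(x, x[retained], y[retained])


def rmse_for(polyline, retained, over: str = "all") -> float:
    """RMSE between the original profile and its simplified interpolation.

    ``over="all"`` (default) averages the squared vertical deviations over
    every original point -- retained points contribute zero.
    ``over="eliminated"`` averages over the eliminated points only; the two
    differ by a constant factor per retained set.
    """
    x, y = _as_xy(polyline)
    deviations = y - interpolate_on_retained(polyline, retained)
    if over == "all":
        return float(np.sqrt(np.mean(deviations**2)))
    if over == "eliminated":
        mask = np.ones(x.size, dtype=bool)
        mask[list(retained)] = False
        if not mask.any():
            return 0.0
        return float(np.sqrt(np.mean(deviations[mask] ** 2)))
    raise ValueError("over must be 'all' or 'eliminated'")


@dataclass(frozen=True)
class ScanRow:
    """One epsilon of the scan: tolerance, retained set, interpolated RMSE."""

    epsilon: float
    retained: tuple[int, ...]
    rmse: float


@dataclass
class SelectionResult:
    """Outcome of RMSE-calibrated point selection.

    ``min3_override`` flags that only the two endpoints satisfied the RMSE
    tolerance and the farthest interior point was added back to avoid a
    chemically meaningless straight-line profile.
    """

    indices: tuple[int, ...]
    epsilon: float
    rmse: float
    min3_override: bool
    scan: list[ScanRow]

    def as_dict(self) -> dict:
        return {
            "indices": list(self.indices),
            "epsilon": self.epsilon,
            "rmse": self.rmse,
            "min3_override": self.min3_override,
            "rmse_convention": "all-points",
        }


def _working_coords(x: np.ndarray, normalize_x: bool) -> np.ndarray:
    if not normalize_x:
        return x
    return (x - x[0]) / (x[-1] - x[0])


def epsilon_max(polyline, normalize_x: bool = False) -> float:
    """Largest perpendicular distance of any point to the first-last chord."""
    x, y = _as_xy(polyline)
    if x.size == 2:
        return 0.0
    distances = _chord_distances(_working_coords(x, normalize_x), y, 0, x.size - 1)
    return float(distances.max())


def epsilon_scan(polyline, step: float = DEFAULT_STEP, normalize_x: bool = True) -> list[ScanRow]:
    """Sweep epsilon from 0 to the maximum chord deviation.

    Rows are produced at 0, step, 2*step, ... and at epsilon_max itself, so
    the scan always ends on the 2-endpoint simplification.  Each row carries
    the retained index set and the all-points interpolated RMSE (computed on
    the original, unscaled coordinates).
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    x, y = _as_xy(polyline)
    work = (_working_coords(x, normalize_x), y)
    eps_top = epsilon_max(polyline, normalize_x=normalize_x)
    grid = [k * step for k in range(int(np.floor(eps_top / step + 1e-12)) + 1)]
    if not grid or grid[-1] < eps_top:
        grid.append(eps_top)
    rows = []
    for eps in grid:
        retained = tuple(rdp(work, eps))
        rows.append(ScanRow(epsilon=float(eps), retained=retained,
                            rmse=rmse_for((x, y), retained)))
    return rows


def select_points(
    polyline,
    rmse_tolerance: float,
    step: float = DEFAULT_STEP,
    normalize_x: bool = True,
) -> SelectionResult:
    """Smallest retained set whose interpolated RMSE meets the tolerance.

    Among scan rows with RMSE <= ``rmse_tolerance`` and at least 3 points,
    the smallest set wins; ties in size resolve toward smaller epsilon
    (lower RMSE).  If only the 2-endpoint simplification qualifies, the
    farthest interior point is added back and the override is flagged.
    """
    if rmse_tolerance < 0:
        raise ValueError("rmse_tolerance must be >= 0")
    x, y = _as_xy(polyline)
    if x.size < 3:
        raise ValueError("point selection needs a polyline with >= 3 points")
    scan = epsilon_scan(polyline, step=step, normalize_x=normalize_x)
    qualifying = [row for row in scan if row.rmse <= rmse_tolerance and len(row.retained) >= 3]
    if qualifying:
        best = min(qualifying, key=lambda row: (len(row.retained), row.epsilon))
        return SelectionResult(
            indices=best.retained,
            epsilon=best.epsilon,
            rmse=best.rmse,
            min3_override=False,
            scan=scan,
        )
    # only 2-point rows met the tolerance: add the farthest interior point back
    fallback = min(
        (row for row in scan if row.rmse <= rmse_tolerance),
        key=lambda row: (len(row.retained), row.epsilon),
    )
    work_x = _working_coords(x, normalize_x)
    distances = _chord_distances(work_x, y, 0, x.size - 1)
    farthest = 1 + int(np.argmax(distances))
    indices = tuple(sorted({0, farthest, x.size - 1}))
    return SelectionResult(
        indices=indices,
        epsilon=fallback.epsilon,
        rmse=rmse_for((x, y), indices),
        min3_override=True,
        scan=scan,
    )
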