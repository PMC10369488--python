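"""Synthetic additive decompositions and energy profiles for testing.

Real partitioned-energy tables come out of expensive quantum-chemistry and
atomic-integration runs; this module generates fully specified stand-ins
that share the statistical structure the REG method assumes -- additivity
of the terms and near-linear term/total relationships -- with controllable
per-term weights, Gaussian noise emulating numerical-integration error,
and exactly reproducible seeded streams.

Two generators are provided:

* :func:`lj_decomposition` -- the canonical two-term worked example: a
  Lennard-Jones 12-6 energy split into its repulsive A/r^12 and attractive
  -B/r^6 parts, whose sum is the total by construction.  The two terms are
  labelled with distinct two-atom pseudo-pairs of ``xc`` kind purely so
  they flow through the term bookkeeping unchanged (a fixture convention,
  not a physical statement).
* :func:`weighted_decomposition` -- N terms that each follow a base curve
  (sigmoid or double-well) scaled by a weight, plus optional i.i.d.
  Gaussian noise per term per point.  With ``exact_total`` the last term
  absorbs the summed noise so the decomposition is exact at every point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .energy_data import Dataset, canonical_label

__all__ = [
    "LJ_REPULSIVE",
    "LJ_ATTRACTIVE",
    "GeneratorSpec",
    "base_curve",
    "lj_decomposition",
    "weighted_decomposition",
    "generate",
]

#: fixture pseudo-pair labels of the two Lennard-Jones terms
LJ_REPULSIVE = canonical_label("xc", "a1", "a2")
LJ_ATTRACTIVE = canonical_label("xc", "b1", "b2")


def lj_decomposition(A: float, B: float, r_grid) -> Dataset:
    """Two-term Lennard-Jones 12-6 decomposition on a distance grid.

    E_rep(r) = A/r^12, E_att(r) = -B/r^6, total their exact sum; the
    minimum of the total sits at r = (2A/B)^(1/6).  Recovery error is zero
    by construction.
    """
    if A <= 0 or B <= 0:
        raise ValueError("A and B must be positive")
    r = np.asarray(r_grid, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r_grid must be strictly positive")
    repulsive = A / r**12
    attractive = -B / r**6
    return Dataset(
        s=r,
        e_total=repulsive + attractive,
        terms={LJ_REPULSIVE: repulsive, LJ_ATTRACTIVE: attractive},
        source=f"lj126(A={A}, B={B})",
    )


def base_curve(kind: str, grid, params: Mapping | None = None) -> np.ndarray:
    """Reference total-energy curve for the weighted generator.

    ``sigmoid``
        smooth monotone rise, one segment.  Params: ``height`` (default
        66.0, the kJ/mol scale of a typical activation barrier), ``center``
        (default mid-grid), ``steepness`` (default 10 / grid range).
    ``double_well``
        quartic with two minima and one interior maximum, three segments.
        Params: ``minima`` pair (default at 1/4 and 3/4 of the grid),
        ``barrier`` height of the central maximum above the wells (default
        66.0), ``tilt`` linear slope added on top (default 0; nonzero tilt
        shifts the analytic extrema).
    """
    s = np.asarray(grid, dtype=float)
    if s.ndim != 1 or s.size < 2 or not np.all(np.diff(s) > 0):
        raise ValueError("grid must be 1-D and strictly increasing")
    params = dict(params or {})
    span = s[-1] - s[0]
    if kind == "sigmoid":
        height = float(params.pop("height", 66.0))
        center = float(params.pop("center", s[0] + span / 2.0))
        steepness = float(params.pop("steepness", 10.0 / span))
        curve = height / (1.0 + np.exp(-steepness * (s - center)))
    elif kind == "double_well":
        default_minima = (s[0] + 0.25 * span, s[0] + 0.75 * span)
        m1, m2 = (float(v) for v in params.pop("minima", default_minima))
        barrier = float(params.pop("barrier", 66.0))
        tilt = float(params.pop("tilt", 0.0))
        shape = (s - m1) ** 2 * (s - m2) ** 2
        peak = ((m2 - m1) / 2.0) ** 4  # value of `shape` at the midpoint
        curve = barrier * shape / peak + tilt * (s - s[0])
    else:
        raise ValueError(f"unknown base curve kind {kind!r}")
    if params:
        raise ValueError(f"unknown base-curve parameter(s) {sorted(params)}")
    return curve


def weighted_decomposition(
    weights,
    grid=None,
    curve: str = "sigmoid",
    curve_params: Mapping | None = None,
    sigma: float = 0.0,
    seed: int = 0,
    exact_total: bool = True,
) -> Dataset:
    """Weighted additive decomposition of a base curve with seeded noise.

    Term i follows ``w_i * E_base(s) + eta_i`` with eta drawn i.i.d.
    Normal(0, sigma^2) from the seeded stream; the total energy is the base
    curve itself.  With ``exact_total`` (requires the weights to sum to 1)
    the last term absorbs the summed noise so the decomposition is exact at
    every point and the REG sum rule holds; without it the noise leaks into
    a nonzero recovery error.  Terms are labelled ``intra(t1) ... intra(tN)``.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size < 1 or not np.all(np.isfinite(w)):
        raise ValueError("weights must be a finite 1-D vector")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if exact_total and not np.isclose(w.sum(), 1.0, rtol=0, atol=1e-12):
        raise ValueError("weights must sum to 1 when exact_total is set")
    s = np.linspace(0.0, 1.0, 11) if grid is None else np.asarray(grid, dtype=float)
    base = base_curve(curve, s, curve_params)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=(w.size, s.size)) if sigma > 0 else np.zeros((w.size, s.size))
    values = w[:, None] * base[None, :] + noise
    if exact_total:
        values[-1] -= noise.sum(axis=0)
    terms = {
        canonical_label("intra", f"t{i + 1}"): values[i] for i in range(w.size)
    }
    return Dataset(
        s=s,
        e_total=base,
        terms=terms,
        source=f"weighted({curve}, n_terms={w.size}, sigma={sigma}, seed={seed})",
    )


@dataclass(frozen=True)
class GeneratorSpec:
    """Fully specified generator input: identical spec + seed => identical data.

    ``model`` is ``"lj126"`` (params ``A``, ``B``) or ``"weighted"``
    (params ``weights``, ``curve``, ``curve_params``, ``sigma``,
    ``exact_total``); ``grid`` is the control-coordinate vector.
    """

    model: str
    grid: tuple[float, ...]
    params: Mapping = field(default_factory=dict)
    seed: int = 0


def generate(spec: GeneratorSpec) -> Dataset:
    """Materialize a :class:`GeneratorSpec` into a :class:`Dataset`."""
    params = dict(spec.params)
    if spec.model == "lj126":
        return lj_decomposition(params.pop("A", 1.0), params.pop("B", 1.0), spec.grid)
    if spec.model == "weighted":
        return weighted_decomposition(
            params.pop("weights"),
            grid=spec.grid,
            curve=params.pop("curve", "sigmoid"),
            curve_params=params.pop("curve_params", None),
            sigma=params.pop("sigma", 0.0),
            seed=spec.seed,
            exact_total=params.pop("exact_total", True),
        )
    raise ValueError(f"unknown generator model {spec.model!r}")
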