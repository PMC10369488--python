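"""Independent reference implementations used to cross-check the package.

These are deliberately written with different algorithms/libraries than the
implementations under test: textbook sum formulas and scipy for the
regression quantities, and a non-recursive stack-based simplifier for RDP.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def ols_slope(x, y) -> float:
    """Textbook OLS slope via raw sums (no mean-translation)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    return float(
        (n * np.sum(x * y) - np.sum(x) * np.sum(y))
        / (n * np.sum(x * x) - np.sum(x) ** 2)
    )


def scipy_slope(x, y) -> float:
    return float(stats.linregress(x, y).slope)


def scipy_pearson(x, y) -> float:
    return float(stats.pearsonr(x, y).statistic)


def point_line_distance(p, a, b) -> float:
    """Cross-product formula for the distance of p to the line a-b."""
    ax, ay = a
    bx, by = b
    px, py = p
    if (ax, ay) == (bx, by):
        return math.hypot(px - ax, py - ay)
    cross = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
    return abs(cross) / math.hypot(bx - ax, by - ay)


def rdp_stack(x, y, epsilon) -> list[int]:
    """Non-recursive stack-based RDP, strict d_max > epsilon, first-index ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = {0, x.size - 1}
    stack = [(0, x.size - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < 2:
            continue
        best_k, best_d = -1, -1.0
        for k in range(i + 1, j):
            d = point_line_distance((x[k], y[k]), (x[i], y[i]), (x[j], y[j]))
            if d > best_d:  # strict: the first maximum wins
                best_k, best_d = k, d
        if best_d > epsilon:
            keep.add(best_k)
            stack.append((i, best_k))
            stack.append((best_k, j))
    return sorted(keep)


def random_decomposition(rng, max_points=20, max_terms=50):
    """Unstructured random dataset for oracle-equivalence checks."""
    from regpes import Dataset, canonical_label

    m = int(rng.integers(4, max_points + 1))
    n_terms = int(rng.integers(1, max_terms + 1))
    s = np.sort(rng.uniform(0.0, 10.0, size=m))
    s += np.arange(m) * 1e-6  # guard against duplicate abscissae
    terms = {
        canonical_label("intra", f"t{i + 1}"): rng.normal(size=m)
        for i in range(n_terms)
    }
    e_total = rng.normal(size=m)
    return Dataset(s=s, e_total=e_total, terms=terms)
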