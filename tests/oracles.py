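"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and, where possible, the
libraries) used by the implementation they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def hull_area_by_triangulation(points) -> float:
    """Convex-hull area as the summed area of a Delaunay triangulation.

    Qhull triangulates the full convex hull, so the triangle areas add up
    to the hull area — an independent route from any direct hull-area
    computation.  Degenerate inputs (collinear, < 3 points) enclose 0.
    """
    from scipy.spatial import Delaunay, QhullError

    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 3:
        return 0.0
    try:
        tri = Delaunay(pts)
    except QhullError:
        return 0.0
    total = 0.0
    for simplex in tri.simplices:
        a, b, c = pts[simplex]
        total += abs((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])) / 2.0
    return total


def count_tree_by_traversal(segments) -> tuple[int, int, int, int]:
    """(n_primary, n_secondary, n_tertiary>=3, n_segments) by walking
    parent links from the roots, ignoring any stored order fields."""
    children: dict[int, list[int]] = {}
    roots = []
    for i, seg in enumerate(segments):
        if seg.parent < 0:
            roots.append(i)
        else:
            children.setdefault(seg.parent, []).append(i)
    counts = [0, 0, 0]
    n_total = 0
    stack = [(r, 1) for r in roots]
    while stack:
        i, depth = stack.pop()
        counts[min(depth, 3) - 1] += 1
        n_total += 1
        for ch in children.get(i, []):
            stack.append((ch, depth + 1))
    return counts[0], counts[1], counts[2], n_total


def mann_whitney_exact_p(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by full enumeration (no ties).

    Returns (U of x, p).  Feasible for n1 + n2 <= ~12.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    assert len(set(pooled)) == len(pooled), "enumeration oracle assumes no ties"
    n1 = len(x)
    idx = range(len(pooled))

    def u_of(subset):
        xs = [pooled[i] for i in subset]
        ys = [pooled[i] for i in idx if i not in subset]
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = sum(1 for a in x for b in y if a > b)
    mean_u = n1 * len(y) / 2.0
    dev = abs(u_obs - mean_u)
    total = count = 0
    for subset in combinations(idx, n1):
        total += 1
        if abs(u_of(set(subset)) - mean_u) >= dev - 1e-12:
            count += 1
    return u_obs, count / total


def chi_square_by_hand(table) -> float:
    """Sum of (O - E)^2 / E with margin-product expected counts."""
    obs = np.asarray(table, dtype=float)
    total = obs.sum()
    chi2 = 0.0
    for i in range(obs.shape[0]):
        for j in range(obs.shape[1]):
            e = obs[i].sum() * obs[:, j].sum() / total
            chi2 += (obs[i, j] - e) ** 2 / e
    return chi2
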