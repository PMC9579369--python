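"""Distances between persistence diagrams: p-Wasserstein and bottleneck.

Two diagrams are compared through partial matchings: every point of one
diagram is either matched to a point of the other or projected onto the
diagonal (cost ``(death - birth) / 2``, the sup-norm distance from a point
to the diagonal).  The bottleneck distance is the minimax single-pair cost
over all such matchings; the p-Wasserstein distance is the minimal p-norm
of all pair costs.  Under the sup-norm ground metric the bottleneck
distance is stable: perturbing the underlying data by d changes the
Vietoris-Rips diagram by at most the perturbation of the distance matrix.

The Wasserstein distance is solved exactly as a square assignment problem
on the diagonal-augmented cost matrix.  The bottleneck distance is solved
by binary search over candidate costs with a bipartite perfect-matching
feasibility test; exact mode searches the finite candidate set, approximate
mode narrows a real bracket until it is shorter than the accuracy ``e``.

Essential (infinite) intervals are excluded by default — matching infinity
against infinity has no canonical cost — or truncated to the filtration
maximum on request.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from .persist import PersistenceDiagram

__all__ = [
    "DiagramMatching",
    "wasserstein_distance",
    "bottleneck_distance",
    "compare_groups",
]

log = logging.getLogger(__name__)


@dataclass
class DiagramMatching:
    """Optimal partial bijection behind a reported distance."""

    pairs: list[tuple[int, int]]
    unmatched_x: list[int]
    unmatched_y: list[int]
    cost: float


def _points(diag: PersistenceDiagram, dim: int, essential: str, eps_max: float) -> np.ndarray:
    """Finite (birth, death) points of one homological dimension."""
    pts = []
    for iv in diag.in_dimension(dim):
        if iv.essential:
            if essential == "drop":
                continue
            if essential == "truncate":
                pts.append((iv.birth, eps_max))
                continue
            raise ValueError(f"unknown essential mode {essential!r}")
        else:
            pts.append((iv.birth, iv.death))
    return np.array(pts, dtype=float).reshape(-1, 2)


def _ground_costs(xp: np.ndarray, yp: np.ndarray, metric: str):
    """Cross costs (n x m) and diagonal-projection costs for each side."""
    if xp.size and yp.size:
        diff = np.abs(xp[:, None, :] - yp[None, :, :])
        cross = diff.max(axis=-1) if metric == "linf" else np.sqrt((diff ** 2).sum(-1))
    else:
        cross = np.zeros((len(xp), len(yp)))
    diag_x = (xp[:, 1] - xp[:, 0]) / 2.0 if len(xp) else np.zeros(0)
    diag_y = (yp[:, 1] - yp[:, 0]) / 2.0 if len(yp) else np.zeros(0)
    if metric == "l2":
        diag_x = diag_x * np.sqrt(2.0)
        diag_y = diag_y * np.sqrt(2.0)
    return cross, diag_x, diag_y


def _check_pair(x: PersistenceDiagram, y: PersistenceDiagram) -> None:
    if abs(x.eps_max - y.eps_max) > 1e-9:
        log.warning("comparing diagrams with different eps_max: %g vs %g",
                    x.eps_max, y.eps_max)


def wasserstein_distance(
    x: PersistenceDiagram,
    y: PersistenceDiagram,
    p: float = 1.0,
    dim: int = 0,
    metric: str = "linf",
    essential: str = "drop",
) -> float:
    """p-Wasserstein distance between the dimension-``dim`` parts of two diagrams.

    Solved exactly: the (n+m) x (n+m) diagonal-augmented cost matrix is fed
    to the Hungarian assignment solver, so every point is matched to a point
    of the other diagram or to its own diagonal projection.
    """
    if p < 1:
        raise ValueError(f"Wasserstein order p must be >= 1, got {p}")
    _check_pair(x, y)
    eps_max = max(x.eps_max, y.eps_max)
    xp = _points(x, dim, essential, eps_max)
    yp = _points(y, dim, essential, eps_max)
    n, m = len(xp), len(yp)
    if n == 0 and m == 0:
        return 0.0
    cross, diag_x, diag_y = _ground_costs(xp, yp, metric)
    size = n + m
    cost = np.zeros((size, size))
    cost[:n, :m] = cross ** p
    cost[:n, m:] = np.inf
    cost[np.arange(n), m + np.arange(n)] = diag_x ** p
    cost[n:, :m] = np.inf
    cost[n + np.arange(m), np.arange(m)] = diag_y ** p
    rows, cols = linear_sum_assignment(cost)
    total = cost[rows, cols].sum()
    return float(total ** (1.0 / p))


def bottleneck_distance(
    x: PersistenceDiagram,
    y: PersistenceDiagram,
    dim: int = 0,
    e: float = 0.0,
    metric: str = "linf",
    essential: str = "drop",
) -> float:
    """Bottleneck distance, exact (``e = 0``) or within accuracy ``e``.

    Exact mode binary-searches the sorted set of candidate costs (all cross
    costs and diagonal projections) — the optimum is always one of them.
    Approximate mode bisects a real bracket until its width is at most
    ``e`` and returns the midpoint, hence within ``e/2`` of the exact value.
    """
    if e < 0:
        raise ValueError(f"accuracy e must be non-negative, got {e}")
    _check_pair(x, y)
    eps_max = max(x.eps_max, y.eps_max)
    xp = _points(x, dim, essential, eps_max)
    yp = _points(y, dim, essential, eps_max)
    if len(xp) == 0 and len(yp) == 0:
        return 0.0
    cross, diag_x, diag_y = _ground_costs(xp, yp, metric)

    def feasible(t: float) -> bool:
        return _perfect_matching_exists(cross, diag_x, diag_y, t)

    if e == 0.0:
        candidates = np.unique(np.concatenate(
            [cross.ravel(), diag_x, diag_y, [0.0]]))
        lo, hi = 0, len(candidates) - 1
        if feasible(candidates[lo]):
            return float(candidates[lo])
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if feasible(candidates[mid]):
                hi = mid
            else:
                lo = mid
        return float(candidates[hi])

    hi = max([cross.max() if cross.size else 0.0,
              diag_x.max() if diag_x.size else 0.0,
              diag_y.max() if diag_y.size else 0.0])
    lo = 0.0
    if feasible(lo):
        return 0.0
    while hi - lo > e:
        mid = (lo + hi) / 2.0
        if feasible(mid):
            hi = mid
        else:
            lo = mid
    return (lo + hi) / 2.0


def _perfect_matching_exists(
    cross: np.ndarray, diag_x: np.ndarray, diag_y: np.ndarray, t: float,
) -> bool:
    """Can every point be matched (cost <= t) in the diagonal-augmented graph?

    Rows are the n points of X plus m virtual diagonal points; columns the m
    points of Y plus n virtual diagonal points.  x_i may use its own
    diagonal slot when its projection cost is within t; virtual-virtual
    pairs are free.
    """
    tol = t + 1e-12
    n, m = cross.shape
    rows, cols = [], []
    xi, yj = np.nonzero(cross <= tol)
    rows.extend(xi)
    cols.extend(yj)
    for i in np.flatnonzero(diag_x <= tol):
        rows.append(i)
        cols.append(m + i)
    for j in np.flatnonzero(diag_y <= tol):
        rows.append(n + j)
        cols.append(j)
    # virtual diagonal rows match any unused virtual column at zero cost
    for j in range(m):
        for i in range(n):
            rows.append(n + j)
            cols.append(m + i)
    size = n + m
    g = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(size, size))
    match = maximum_bipartite_matching(g, perm_type="column")
    return int((match >= 0).sum()) == size


def bottleneck_by_enumeration(
    x: PersistenceDiagram, y: PersistenceDiagram, dim: int = 0,
    metric: str = "linf", essential: str = "drop",
) -> float:
    """Exhaustive minimax over all partial matchings (tiny diagrams only)."""
    eps_max = max(x.eps_max, y.eps_max)
    xp = _points(x, dim, essential, eps_max)
    yp = _points(y, dim, essential, eps_max)
    if len(xp) > 7 or len(yp) > 7:
        raise ValueError("enumeration limited to 7 points per diagram")
    cross, diag_x, diag_y = _ground_costs(xp, yp, metric)
    n, m = len(xp), len(yp)
    best = np.inf
    for k in range(min(n, m) + 1):
        for xs in itertools.combinations(range(n), k):
            rest_x = [i for i in range(n) if i not in xs]
            for ys in itertools.permutations(range(m), k):
                rest_y = [j for j in range(m) if j not in ys]
                costs = [cross[i, j] for i, j in zip(xs, ys)]
                costs += [diag_x[i] for i in rest_x]
                costs += [diag_y[j] for j in rest_y]
                best = min(best, max(costs, default=0.0))
    return float(best)


def compare_groups(
    diagrams_a: dict[str, PersistenceDiagram] | list[PersistenceDiagram],
    diagrams_b: dict[str, PersistenceDiagram] | list[PersistenceDiagram],
    dims: tuple[int, ...] = (0, 1),
    p_orders: tuple[float, ...] = (1.0,),
    e: float = 0.01,
    metric: str = "linf",
) -> pd.DataFrame:
    """Per-band table of diagram distances between two groups.

    Rows are bands (or positional labels), columns are, per homological
    dimension: exact bottleneck, approximate bottleneck at accuracy ``e``
    and the requested Wasserstein orders.
    """
    a = dict(diagrams_a) if isinstance(diagrams_a, dict) else {
        str(k): v for k, v in enumerate(diagrams_a)}
    b = dict(diagrams_b) if isinstance(diagrams_b, dict) else {
        str(k): v for k, v in enumerate(diagrams_b)}
    if not a or not b:
        raise ValueError("both groups must contain at least one diagram")
    if set(a) != set(b):
        raise ValueError(f"band labels differ: {sorted(a)} vs {sorted(b)}")
    records = {}
    for band in a:
        row = {}
        for dim in dims:
            row[f"dim{dim}_bottleneck"] = bottleneck_distance(
                a[band], b[band], dim=dim, e=0.0, metric=metric)
            row[f"dim{dim}_bottleneck_e{e:g}"] = bottleneck_distance(
                a[band], b[band], dim=dim, e=e, metric=metric)
            for p in p_orders:
                row[f"dim{dim}_wasserstein_p{p:g}"] = wasserstein_distance(
                    a[band], b[band], p=p, dim=dim, metric=metric)
        records[band] = row
    return pd.DataFrame.from_dict(records, orient="index")
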