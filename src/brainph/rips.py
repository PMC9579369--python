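"""Vietoris-Rips filtration of a point cloud or distance matrix.

At scale ``eps`` the Vietoris-Rips complex contains a simplex on a vertex
set whenever all pairwise distances within the set are at most ``eps``.
Sweeping ``eps`` from 0 to a maximum threshold yields a nested family of
simplicial complexes — the filtration — in which every simplex carries the
scale at which it first appears (its *filtration value*): 0 for vertices,
the maximum pairwise distance among its vertices otherwise.

Two value modes are supported:

* **exact** — entry values are the true maximum pairwise distances;
* **grid (Fs)** — values are snapped *up* to a uniform grid of ``Fs`` steps
  on ``[0, eps_max]``, mirroring the step parameter of barcode software; a
  simplex is never snapped below its true appearance scale, so the snapped
  filtration is still a filtration.

Construction is by incremental expansion over lower neighbours, equivalent
to (but much faster than) enumerating all vertex subsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .netbuild import DistanceMatrix

__all__ = ["Simplex", "Filtration", "rips_filtration", "count_by_dimension"]


@dataclass(frozen=True, order=True)
class Simplex:
    """A simplex identified by its strictly increasing vertex tuple."""

    vertices: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.vertices:
            raise ValueError("a simplex needs at least one vertex")
        if any(a >= b for a, b in zip(self.vertices, self.vertices[1:])):
            raise ValueError(f"vertices must be strictly increasing: {self.vertices}")

    @property
    def dimension(self) -> int:
        return len(self.vertices) - 1

    def faces(self) -> list["Simplex"]:
        """Codimension-1 faces (empty for vertices)."""
        if self.dimension == 0:
            return []
        v = self.vertices
        return [Simplex(v[:k] + v[k + 1:]) for k in range(len(v))]


@dataclass
class Filtration:
    """Simplices with appearance values, sorted by (value, dimension, vertices)."""

    simplices: list[tuple[Simplex, float]]
    max_dimension: int
    eps_max: float
    fs: int | None = None
    n_vertices: int = 0

    def __post_init__(self) -> None:
        self.simplices = sorted(
            self.simplices, key=lambda sv: (sv[1], sv[0].dimension, sv[0].vertices)
        )
        if not self.n_vertices:
            self.n_vertices = sum(1 for s, _ in self.simplices if s.dimension == 0)

    def __len__(self) -> int:
        return len(self.simplices)

    def __iter__(self):
        return iter(self.simplices)

    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.simplices])

    def check_closure(self) -> None:
        """Raise if any face is missing or appears after one of its cofaces."""
        value_of = {s.vertices: v for s, v in self.simplices}
        for s, v in self.simplices:
            for f in s.faces():
                fv = value_of.get(f.vertices)
                if fv is None:
                    raise ValueError(f"face {f.vertices} of {s.vertices} missing")
                if fv > v + 1e-12:
                    raise ValueError(
                        f"face {f.vertices} (value {fv}) appears after coface "
                        f"{s.vertices} (value {v})"
                    )

    def to_text(self, path: str | Path) -> Path:
        """Rows of ``value dimension v0 v1 ...`` in filtration order."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("# value dimension vertices...\n")
            for s, v in self.simplices:
                fh.write(f"{float(v)!r} {s.dimension} "
                         + " ".join(map(str, s.vertices)) + "\n")
        return path


def rips_filtration(
    d: DistanceMatrix | np.ndarray,
    max_dim: int = 2,
    eps_max: float | None = None,
    fs: int | None = None,
) -> Filtration:
    """Build the Vietoris-Rips filtration up to ``max_dim`` and ``eps_max``.

    Parameters
    ----------
    d
        A :class:`~brainph.netbuild.DistanceMatrix` or a raw symmetric
        distance array.
    max_dim
        Largest simplex dimension to build.  To read off homology in
        dimension p the filtration must contain (p+1)-simplices, so pass
        ``max_dim = p + 1`` when deaths in dimension p matter.
    eps_max
        Maximum filtration threshold; ``None`` uses the maximum pairwise
        distance, which makes the sweep full-scale (every edge appears).
    fs
        Optional number of filtering steps: appearance values are snapped up
        to the grid ``{i * eps_max / fs}``.
    """
    values = d.values if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    n = values.shape[0]
    if max_dim < 0:
        raise ValueError("max_dim must be non-negative")
    if eps_max is None:
        eps_max = float(values.max()) if n > 1 else 1.0
    if eps_max <= 0:
        raise ValueError("eps_max must be positive")
    if fs is not None and fs < 1:
        raise ValueError("fs must be a positive step count")

    # lower-neighbour sets: j < i with d(i, j) <= eps_max
    lower: list[np.ndarray] = []
    for i in range(n):
        js = np.flatnonzero(values[i, :i] <= eps_max)
        lower.append(js)

    out: list[tuple[Simplex, float]] = [(Simplex((i,)), 0.0) for i in range(n)]
    # incremental expansion: extend each simplex by common lower neighbours
    frontier: list[tuple[tuple[int, ...], np.ndarray, float]] = []
    if max_dim >= 1:
        for i in range(n):
            for j in lower[i]:
                val = float(values[i, j])
                nbrs = np.intersect1d(lower[i], lower[j], assume_unique=True)
                frontier.append(((int(j), i), nbrs, val))
                out.append((Simplex((int(j), i)), val))
    dim = 1
    while dim < max_dim and frontier:
        nxt: list[tuple[tuple[int, ...], np.ndarray, float]] = []
        for verts, nbrs, val in frontier:
            for u in nbrs:
                u = int(u)
                new_val = max(val, float(values[u, list(verts)].max()))
                if new_val > eps_max:
                    continue
                new_verts = (u, *verts)
                new_nbrs = np.intersect1d(nbrs, lower[u], assume_unique=True)
                nxt.append((new_verts, new_nbrs, new_val))
                out.append((Simplex(tuple(sorted(new_verts))), new_val))
        frontier = nxt
        dim += 1

    if fs is not None:
        step = eps_max / fs
        out = [(s, 0.0 if v == 0 else min(math.ceil(v / step - 1e-12) * step, eps_max))
               for s, v in out]
    return Filtration(out, max_dimension=max_dim, eps_max=eps_max, fs=fs, n_vertices=n)


def count_by_dimension(f: Filtration) -> dict[int | str, int]:
    """Simplex counts per dimension plus the total, e.g. ``{0: 4, 1: 6, 'total': 10}``."""
    counts: dict[int | str, int] = {d: 0 for d in range(f.max_dimension + 1)}
    for s, _ in f.simplices:
        counts[s.dimension] += 1
    counts["total"] = len(f.simplices)
    return counts
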