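"""Persistent homology of a filtration over the two-element field.

Homology classes of the growing complex are tracked across the filtration:
each class is born at some scale, and either dies when it becomes a
boundary or survives to the end (an *essential* class, recorded with death
infinity).  Dimension 0 classes are connected components, dimension 1
tunnels/loops, dimension 2 voids.  The multiset of (dimension, birth,
death) intervals is the persistence diagram; drawn as horizontal bars it is
the barcode.

The main routine reduces the boundary matrix by left-to-right column
additions in filtration order, processing dimensions from the top down so
that columns whose simplices are already known to create cycles can be
cleared without reduction (the "twist" optimisation).  Columns are stored
as Python-integer bitsets, which makes the inner XOR loop a single machine
operation per word.

Classes in the filtration's top simplex dimension are not reported: their
deaths would require simplices one dimension higher, so a filtration built
to ``max_dim = d`` yields homology in dimensions 0 .. d-1 (pass
``max_dim = p + 1`` to resolve dimension p).

:func:`brute_force_oracle` recomputes the same diagram by an entirely
different route — Gaussian-elimination ranks of boundary submatrices at
every pair of filtration values, combined by inclusion-exclusion — and is
used to cross-check the reduction on small inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .rips import Filtration, Simplex

__all__ = [
    "PersistenceInterval",
    "PersistenceDiagram",
    "persistent_homology",
    "betti_numbers_at",
    "brute_force_oracle",
    "classify_intervals",
]

INF = math.inf


@dataclass(frozen=True, order=True)
class PersistenceInterval:
    """One homology class: born at ``birth``, dead at ``death`` (inf = essential)."""

    dimension: int
    birth: float
    death: float

    def __post_init__(self) -> None:
        if not (self.death > self.birth):
            raise ValueError(f"death must exceed birth: {self}")

    @property
    def length(self) -> float:
        return self.death - self.birth

    @property
    def essential(self) -> bool:
        return math.isinf(self.death)


@dataclass
class PersistenceDiagram:
    """Multiset of persistence intervals with bookkeeping of the run."""

    intervals: list[PersistenceInterval]
    max_dimension: int
    eps_max: float
    provenance: str = ""

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals)
        for iv in self.intervals:
            if iv.birth < 0:
                raise ValueError(f"negative birth: {iv}")
            if not iv.essential and iv.death > self.eps_max + 1e-9:
                raise ValueError(f"finite death beyond eps_max: {iv}")

    def __len__(self) -> int:
        return len(self.intervals)

    def in_dimension(self, dim: int) -> list[PersistenceInterval]:
        return [iv for iv in self.intervals if iv.dimension == dim]

    def as_multiset(self, ndigits: int = 9) -> dict:
        """Rounded (dim, birth, death) -> multiplicity; used for exact comparison."""
        out: dict = {}
        for iv in self.intervals:
            key = (iv.dimension, round(iv.birth, ndigits),
                   INF if iv.essential else round(iv.death, ndigits))
            out[key] = out.get(key, 0) + 1
        return out

    def to_text(self, path: str | Path) -> Path:
        """Columns ``dimension birth death`` with ``inf`` for essential classes."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# persistence diagram, eps_max={self.eps_max!r}, "
                     f"max_dimension={self.max_dimension}\n")
            fh.write("dimension\tbirth\tdeath\n")
            for iv in self.intervals:
                death = "inf" if iv.essential else repr(float(iv.death))
                fh.write(f"{iv.dimension}\t{float(iv.birth)!r}\t{death}\n")
        return path

    @classmethod
    def from_text(cls, path: str | Path) -> "PersistenceDiagram":
        eps_max, max_dim = 1.0, 0
        intervals = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    for tok in line[1:].split(","):
                        tok = tok.strip()
                        if tok.startswith("eps_max="):
                            eps_max = float(tok[8:])
                        elif tok.startswith("max_dimension="):
                            max_dim = int(tok[14:])
                    continue
                if line.startswith("dimension"):
                    continue
                d, b, dth = line.split()
                intervals.append(PersistenceInterval(
                    int(d), float(b), INF if dth == "inf" else float(dth)))
        return cls(intervals, max_dim, eps_max, provenance=f"loaded from {Path(path).name}")


# ---------------------------------------------------------------------------
# Boundary-matrix reduction
# ---------------------------------------------------------------------------

def persistent_homology(f: Filtration, validate: bool = True) -> PersistenceDiagram:
    """Persistence intervals of a filtration by twist column reduction.

    Zero-length intervals (birth equal to death, invisible in barcodes) are
    discarded.  The number of dimension-0 intervals, finite plus essential,
    always equals the vertex count.
    """
    if validate:
        f.check_closure()
    simplices = f.simplices
    index_of = {s.vertices: idx for idx, (s, _) in enumerate(simplices)}
    values = [v for _, v in simplices]
    dims = [s.dimension for s, _ in simplices]

    by_dim: dict[int, list[int]] = {}
    for idx, d in enumerate(dims):
        by_dim.setdefault(d, []).append(idx)

    reduced: dict[int, int] = {}    # column index -> reduced bitset
    pivot_of: dict[int, int] = {}   # pivot row -> column index
    pairs: list[tuple[int, int]] = []
    cleared: set[int] = set()

    for d in range(f.max_dimension, 0, -1):
        for j in by_dim.get(d, []):
            if j in cleared:
                continue
            col = 0
            for face in simplices[j][0].faces():
                col ^= 1 << index_of[face.vertices]
            while col:
                low = col.bit_length() - 1
                owner = pivot_of.get(low)
                if owner is None:
                    pivot_of[low] = j
                    reduced[j] = col
                    pairs.append((low, j))
                    cleared.add(low)
                    break
                col ^= reduced[owner]

    report_max = max(0, f.max_dimension - 1)
    intervals: list[PersistenceInterval] = []
    for i, j in pairs:
        if values[j] > values[i]:
            intervals.append(PersistenceInterval(dims[i], values[i], values[j]))
    paired_births = {i for i, _ in pairs}
    paired_deaths = {j for _, j in pairs}
    for idx in range(len(simplices)):
        if idx in paired_births or idx in paired_deaths:
            continue
        # unpaired simplex: creates a class that never dies; classes in the
        # top simplex dimension are unresolved (no cofaces built) and dropped
        if dims[idx] <= report_max:
            intervals.append(PersistenceInterval(dims[idx], values[idx], INF))
    return PersistenceDiagram(intervals, report_max, f.eps_max,
                              provenance="persistent_homology")


def betti_numbers_at(diag: PersistenceDiagram, eps: float) -> dict[int, int]:
    """Betti numbers read off the diagram: classes with ``birth <= eps < death``."""
    if not 0 <= eps <= diag.eps_max:
        raise ValueError(f"eps={eps} outside [0, {diag.eps_max}]")
    betti = {d: 0 for d in range(diag.max_dimension + 1)}
    for iv in diag.intervals:
        if iv.birth <= eps < iv.death:
            betti[iv.dimension] += 1
    return betti


def classify_intervals(
    diag: PersistenceDiagram, min_length: float,
) -> tuple[list[PersistenceInterval], list[PersistenceInterval]]:
    """Split intervals into (persistent features, noise) by bar length.

    Long bars are structure, short bars noise; essential classes are always
    persistent regardless of ``min_length``.
    """
    if min_length < 0:
        raise ValueError("min_length must be non-negative")
    persistent, noise = [], []
    for iv in diag.intervals:
        if iv.essential or iv.length >= min_length:
            persistent.append(iv)
        else:
            noise.append(iv)
    return persistent, noise


# ---------------------------------------------------------------------------
# Independent oracle: persistent Betti numbers from boundary ranks
# ---------------------------------------------------------------------------

ORACLE_MAX_SIMPLICES = 2000


def brute_force_oracle(f: Filtration) -> PersistenceDiagram:
    """Recompute the diagram from Gaussian-elimination ranks over GF(2).

    For every pair of filtration values ``a <= b`` the persistent Betti
    number ``beta_p(a, b)`` (classes alive from a through b) is computed
    from ranks of boundary submatrices; interval multiplicities follow by
    inclusion-exclusion.  Exponentially slower than the reduction but
    shares no code with it.  Refuses inputs above a small size bound.
    """
    if len(f) > ORACLE_MAX_SIMPLICES:
        raise ValueError(
            f"oracle limited to {ORACLE_MAX_SIMPLICES} simplices, got {len(f)}")
    report_max = max(0, f.max_dimension - 1)
    if len(f) == 0:
        return PersistenceDiagram([], report_max, f.eps_max, provenance="oracle")

    vals = sorted({v for _, v in f.simplices})
    m = len(vals)
    max_dim = f.max_dimension

    # per dimension: ordered simplex list, their values, index lookup
    simp: dict[int, list[Simplex]] = {d: [] for d in range(max_dim + 1)}
    sval: dict[int, list[float]] = {d: [] for d in range(max_dim + 1)}
    for s, v in f.simplices:
        simp[s.dimension].append(s)
        sval[s.dimension].append(v)
    pos: dict[int, dict[tuple, int]] = {
        d: {s.vertices: k for k, s in enumerate(simp[d])} for d in range(max_dim + 1)
    }

    # boundary columns of (p+1)-simplices as bitsets over p-simplex rows
    def boundary_columns(p: int) -> list[tuple[float, int]]:
        cols = []
        for s, v in zip(simp[p + 1], sval[p + 1]):
            bits = 0
            for face in s.faces():
                bits |= 1 << pos[p][face.vertices]
            cols.append((v, bits))
        return cols

    def rank(columns: list[int]) -> int:
        r = 0
        basis: list[int] = []
        for col in columns:
            for b in basis:
                if col & (1 << (b.bit_length() - 1)):
                    col ^= b
            if col:
                basis.append(col)
                basis.sort(key=int.bit_length, reverse=True)
                r += 1
        return r

    # beta[p][i][j]: classes of dim p alive on [vals[i], vals[j]]
    beta = np.zeros((report_max + 1, m, m), dtype=int)
    for p in range(report_max + 1):
        n_p_at = [sum(1 for v in sval[p] if v <= a) for a in vals]
        d_p = boundary_columns(p - 1) if p >= 1 else []
        rank_dp_at = [rank([bits for v, bits in d_p if v <= a]) for a in vals]
        d_q = boundary_columns(p) if p + 1 <= max_dim else []
        for jb, b in enumerate(vals):
            cols_b = [bits for v, bits in d_q if v <= b]
            rank_b = rank(cols_b)
            for ia in range(jb + 1):
                a = vals[ia]
                # mask rows of p-simplices born after a
                mask = 0
                for k, v in enumerate(sval[p]):
                    if v > a:
                        mask |= 1 << k
                rank_b_late = rank([bits & mask for bits in cols_b])
                z_a = n_p_at[ia] - (rank_dp_at[ia] if p >= 1 else 0)
                b_cap = rank_b - rank_b_late
                beta[p, ia, jb] = z_a - b_cap

    intervals: list[PersistenceInterval] = []
    for p in range(report_max + 1):
        for ia in range(m):
            prev_a = beta[p, ia - 1] if ia > 0 else np.zeros(m, dtype=int)
            # finite intervals [vals[ia], vals[jb]) for jb > ia
            for jb in range(ia + 1, m):
                mult = (beta[p, ia, jb - 1] - beta[p, ia, jb]) \
                    - (prev_a[jb - 1] - prev_a[jb])
                for _ in range(int(mult)):
                    intervals.append(
                        PersistenceInterval(p, vals[ia], vals[jb]))
            mult_ess = beta[p, ia, m - 1] - prev_a[m - 1]
            for _ in range(int(mult_ess)):
                intervals.append(PersistenceInterval(p, vals[ia], INF))
    return PersistenceDiagram(intervals, report_max, f.eps_max, provenance="oracle")
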