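"""Construction of the weighted functional-connectivity network.

The network nodes are recording channels (electrodes).  Edge weights are
derived from the sample Pearson correlation between channel signals; the
distance between two nodes is the reciprocal of the correlation magnitude,
``d_ij = min(1 / |r_ij|, cap)``, so strongly (anti-)correlated channels sit
close together and uncorrelated channels are pushed out to a finite cap.
The cap keeps distances finite when a correlation vanishes; anything below
``1 / cap`` in magnitude is treated as "no measurable coupling".

Binary adjacency views at a given connection density (fraction of retained
strongest edges) are provided for inspection and plotting only; the
persistent-homology pipeline never binarises.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .recording import MultichannelRecording

__all__ = [
    "CorrelationMatrix",
    "DistanceMatrix",
    "EdgeWeightList",
    "pearson_matrix",
    "reciprocal_distance",
    "threshold_by_density",
    "write_edge_weights",
    "max_threshold",
    "DEFAULT_CAP",
]

#: Default distance assigned to (near-)zero correlations: 1/|r| is clipped here.
DEFAULT_CAP = 1000.0


@dataclass
class CorrelationMatrix:
    """Symmetric matrix of sample Pearson correlations with unit diagonal."""

    values: np.ndarray
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.abs(v) > 1 + 1e-10):
            raise ValueError("correlations must lie in [-1, 1]")
        self.values = v
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(len(v))]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def to_text(self, path: str | Path) -> Path:
        return _write_labelled_matrix(self.values, self.channel_labels, path)

    @classmethod
    def from_text(cls, path: str | Path) -> "CorrelationMatrix":
        values, labels = _read_labelled_matrix(path)
        return cls(values, labels)


@dataclass
class DistanceMatrix:
    """Symmetric inter-node distances: zero diagonal, positive finite off-diagonal."""

    values: np.ndarray
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have zero diagonal")
        off = v[~np.eye(len(v), dtype=bool)]
        if off.size and (np.any(off <= 0) or np.any(~np.isfinite(off))):
            raise ValueError("off-diagonal distances must be positive and finite")
        self.values = v
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(len(v))]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def to_text(self, path: str | Path) -> Path:
        return _write_labelled_matrix(self.values, self.channel_labels, path)

    @classmethod
    def from_text(cls, path: str | Path) -> "DistanceMatrix":
        values, labels = _read_labelled_matrix(path)
        return cls(values, labels)


@dataclass
class EdgeWeightList:
    """Upper-triangle edge list: rows ``(i, j, w_ij)`` with ``i < j``.

    Node indices are 0-based in memory; text exports are 1-based (stated in
    the file header) to match hand-audited edge-weight files.
    """

    i: np.ndarray
    j: np.ndarray
    weight: np.ndarray
    n_nodes: int
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.i = np.asarray(self.i, dtype=int)
        self.j = np.asarray(self.j, dtype=int)
        self.weight = np.asarray(self.weight, dtype=float)
        if not (len(self.i) == len(self.j) == len(self.weight)):
            raise ValueError("i, j, weight must have equal length")
        if np.any(self.i >= self.j):
            raise ValueError("edge rows must satisfy i < j")

    def __len__(self) -> int:
        return len(self.weight)

    def to_distance_matrix(self) -> DistanceMatrix:
        """Rebuild the symmetric matrix; inverse of :func:`write_edge_weights`."""
        n = self.n_nodes
        m = np.zeros((n, n))
        m[self.i, self.j] = self.weight
        m += m.T
        return DistanceMatrix(m, list(self.channel_labels))

    def to_text(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# edge weights, 1-based node indices, n_nodes={self.n_nodes}\n")
            for a, b, w in zip(self.i, self.j, self.weight):
                fh.write(f"{a + 1} {b + 1} {float(w)!r}\n")
        return path

    @classmethod
    def from_text(cls, path: str | Path) -> "EdgeWeightList":
        n_nodes = 0
        ii, jj, ww = [], [], []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    if "n_nodes=" in line:
                        n_nodes = int(line.rsplit("n_nodes=", 1)[1])
                    continue
                a, b, w = line.split()
                ii.append(int(a) - 1)
                jj.append(int(b) - 1)
                ww.append(float(w))
        n_nodes = n_nodes or (max(jj) + 1 if jj else 0)
        return cls(np.array(ii), np.array(jj), np.array(ww), n_nodes)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def pearson_matrix(rec: MultichannelRecording) -> CorrelationMatrix:
    """Sample Pearson correlation between every pair of channels.

    Raises if any channel is constant: its correlation is undefined and a
    flat channel in real data means a dead electrode.
    """
    if rec.n_samples < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    sd = rec.data.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = ", ".join(rec.channel_labels[k] for k in dead)
        raise ValueError(f"zero-variance channel(s): {names}")
    r = np.corrcoef(rec.data)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r, list(rec.channel_labels))


def reciprocal_distance(corr: CorrelationMatrix, cap: float = DEFAULT_CAP) -> DistanceMatrix:
    """Distance matrix ``d_ij = min(1 / |r_ij|, cap)``, zero on the diagonal.

    The magnitude is used so anti-correlated channels count as coupled; the
    cap bounds the distance of uncorrelated pairs.
    """
    if cap <= 1:
        raise ValueError(f"cap must exceed 1 (got {cap}); 1/|r| >= 1 for all r")
    with np.errstate(divide="ignore"):
        d = 1.0 / np.abs(corr.values)
    d = np.minimum(d, cap)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, list(corr.channel_labels))


def threshold_by_density(
    corr: CorrelationMatrix, density: float, *, include_ties: bool = True,
) -> np.ndarray:
    """Binary adjacency keeping the ``floor(density * C(n,2))`` strongest ``|r|``.

    A tie group straddling the cutoff is kept whole (deterministic,
    order-independent output), so the realised edge count may exceed the
    target by the tie-group size; pass ``include_ties=False`` to truncate at
    the target count in (stable) sort order instead.
    """
    if not 0.0 <= density <= 1.0:
        raise ValueError(f"density must be in [0, 1], got {density}")
    n = corr.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    strength = np.abs(corr.values[iu, ju])
    n_keep = int(np.floor(density * len(strength)))
    adj = np.zeros((n, n), dtype=int)
    if n_keep == 0:
        return adj
    order = np.argsort(-strength, kind="stable")
    if include_ties and n_keep < len(strength):
        cut = strength[order[n_keep - 1]]
        keep = np.flatnonzero(strength >= cut)
    else:
        keep = order[:n_keep]
    adj[iu[keep], ju[keep]] = 1
    adj |= adj.T
    return adj


def write_edge_weights(d: DistanceMatrix) -> EdgeWeightList:
    """Flatten the upper triangle into ``(i, j, w)`` rows in lexicographic order."""
    iu, ju = np.triu_indices(d.n_nodes, k=1)
    return EdgeWeightList(iu, ju, d.values[iu, ju], d.n_nodes, list(d.channel_labels))


def max_threshold(d: DistanceMatrix) -> float:
    """Largest inter-node distance: the natural upper filtration threshold.

    Running the Vietoris-Rips filtration to this value guarantees the final
    complex contains every edge, making the analysis threshold-free.
    """
    if d.n_nodes < 2:
        raise ValueError("need at least 2 nodes for a maximum distance")
    iu, ju = np.triu_indices(d.n_nodes, k=1)
    return float(d.values[iu, ju].max())


# ---------------------------------------------------------------------------
# labelled-matrix text helpers
# ---------------------------------------------------------------------------

def _write_labelled_matrix(values: np.ndarray, labels: list[str], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(labels) + "\n")
        np.savetxt(fh, values, delimiter="\t")
    return path


def _read_labelled_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    with open(path) as fh:
        labels = fh.readline().strip().split("\t")
        values = np.loadtxt(fh, ndmin=2)
    return values, labels
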