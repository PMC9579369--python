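"""ISOMAP embedding of a distance matrix into a low-dimensional point cloud.

The reciprocal-correlation distances between electrodes are generally not
Euclidean.  ISOMAP turns them into node coordinates in three steps:

1. build a symmetric k-nearest-neighbour graph weighted by the input
   distances (an edge is kept when either endpoint selects it);
2. compute exact all-pairs shortest paths on that graph (the geodesic
   approximation of the underlying manifold metric);
3. embed the geodesic matrix with classical multidimensional scaling,
   keeping the components whose eigenvalues are positive.

With a complete neighbour graph (``k = n - 1``) the geodesics equal the
input distances and the procedure reduces to classical MDS — an exact
embedding whenever the input distances are Euclidean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .netbuild import DistanceMatrix

__all__ = ["PointCloud", "EmbeddingReport", "isomap", "classical_mds",
           "write_point_cloud", "read_point_cloud"]

#: Relative eigenvalue cutoff for automatic dimension selection.
EIGENVALUE_RTOL = 1e-8

log = logging.getLogger(__name__)


@dataclass
class PointCloud:
    """``n x m`` coordinates of n points in m dimensions."""

    coordinates: np.ndarray
    labels: list[str] = field(default_factory=list)
    source_note: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.coordinates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        if c.size == 0 or not np.all(np.isfinite(c)):
            raise ValueError("coordinates must be a non-empty finite matrix")
        self.coordinates = c
        if not self.labels:
            self.labels = [f"p{i:02d}" for i in range(len(c))]

    @property
    def n_points(self) -> int:
        return self.coordinates.shape[0]

    @property
    def dim(self) -> int:
        return self.coordinates.shape[1]

    def distance_matrix(self) -> np.ndarray:
        """Pairwise Euclidean distances between the points."""
        diff = self.coordinates[:, None, :] - self.coordinates[None, :, :]
        return np.sqrt((diff ** 2).sum(axis=-1))


@dataclass
class EmbeddingReport:
    """Diagnostics of one ISOMAP run."""

    chosen_dim: int
    eigenvalues: np.ndarray          # descending, all retained + leading dropped
    residual_variance: np.ndarray    # per candidate dim 1..chosen_dim
    neighbor_param: int
    negative_eigenvalue_mass: float  # |sum of negative eigenvalues| (non-Euclidean part)
    reconstruction_error: float      # Frobenius norm between geodesics and embedded distances


def isomap(
    d: DistanceMatrix,
    k: int = 7,
    target_dim: int | None = None,
    auto_connect: bool = False,
) -> tuple[PointCloud, EmbeddingReport]:
    """Embed a distance matrix; returns coordinates plus diagnostics.

    Parameters
    ----------
    d
        Symmetric inter-node distances.
    k
        Neighbour count for the k-NN graph. ``k = n - 1`` gives the complete
        graph (pure classical MDS of ``d``).
    target_dim
        Requested embedding dimension; ``None`` keeps every component with
        eigenvalue above ``1e-8`` times the leading one (capped at n - 1).
    auto_connect
        When the k-NN graph is disconnected, raise k to the smallest
        connecting value (logged) instead of erroring.

    Raises
    ------
    ValueError
        If the k-NN graph is disconnected and ``auto_connect`` is off; the
        message reports the number of components and the smallest
        connecting k.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    n = d.n_nodes
    k = min(k, n - 1)
    graph = _knn_graph(d.values, k)
    n_comp, _ = connected_components(graph, directed=False)
    if n_comp > 1:
        k_min = _minimal_connecting_k(d.values)
        if not auto_connect:
            raise ValueError(
                f"k-NN graph with k={k} has {n_comp} connected components; "
                f"smallest connecting k is {k_min}"
            )
        log.info("k-NN graph disconnected at k=%d; raising to k=%d", k, k_min)
        k = k_min
        graph = _knn_graph(d.values, k)
    geodesic = shortest_path(graph, method="D", directed=False)
    coords, eigvals = classical_mds(geodesic, target_dim)
    chosen = coords.shape[1]

    pos = eigvals[eigvals > 0]
    total = pos.sum() if pos.size else 1.0
    kept = eigvals[:chosen]
    residual = 1.0 - np.cumsum(np.clip(kept, 0, None)) / total
    emb = PointCloud(coords, list(d.channel_labels),
                     source_note=f"isomap(k={k}, dim={chosen})")
    recon = np.linalg.norm(geodesic - emb.distance_matrix())
    report = EmbeddingReport(
        chosen_dim=chosen,
        eigenvalues=eigvals,
        residual_variance=residual,
        neighbor_param=k,
        negative_eigenvalue_mass=float(-eigvals[eigvals < 0].sum()),
        reconstruction_error=float(recon),
    )
    return emb, report


def classical_mds(
    dist: np.ndarray, target_dim: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) MDS of a square distance matrix.

    Returns ``(coordinates, eigenvalues)`` with eigenvalues in descending
    order.  Only components with positive eigenvalues carry coordinates;
    negative eigenvalues signal non-Euclidean input and are dropped.
    """
    n = dist.shape[0]
    if n == 1:
        return np.zeros((1, 1)), np.zeros(1)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dist ** 2) @ j
    b = (b + b.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > EIGENVALUE_RTOL * max(eigvals[0], 0.0)
    max_dim = min(int(positive.sum()), n - 1)
    dim = max_dim if target_dim is None else min(target_dim, max_dim)
    dim = max(dim, 1)
    coords = eigvecs[:, :dim] * np.sqrt(np.clip(eigvals[:dim], 0, None))
    return coords, eigvals


def write_point_cloud(pc: PointCloud, path: str | Path) -> Path:
    """Whitespace-delimited coordinates, one point per row (JavaPlex-style .txt)."""
    path = Path(path)
    with open(path, "w") as fh:
        for row in pc.coordinates:
            fh.write(" ".join(repr(float(x)) for x in row) + "\n")
    return path


def read_point_cloud(path: str | Path) -> PointCloud:
    coords = np.loadtxt(path, ndmin=2)
    return PointCloud(coords, source_note=f"loaded from {Path(path).name}")


def _knn_graph(dist: np.ndarray, k: int) -> csr_matrix:
    """Symmetric k-NN graph: edge kept when either endpoint selects it."""
    n = dist.shape[0]
    masked = dist + np.diag(np.full(n, np.inf))
    nn = np.argsort(masked, axis=1, kind="stable")[:, :k]
    rows = np.repeat(np.arange(n), k)
    cols = nn.ravel()
    w = dist[rows, cols]
    m = csr_matrix((w, (rows, cols)), shape=(n, n))
    return m.maximum(m.T)


def _minimal_connecting_k(dist: np.ndarray) -> int:
    n = dist.shape[0]
    for k in range(1, n):
        n_comp, _ = connected_components(_knn_graph(dist, k), directed=False)
        if n_comp == 1:
            return k
    return n - 1
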