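"""Synthetic multichannel recordings and geometric point-cloud fixtures.

Clinical task EEG of the kind this toolkit targets is rarely shareable, so
the package ships a generator that emulates its statistical shape: a
60-channel recording whose channels fall into functional blocks with a
chosen within-block and between-block Pearson correlation.  Signals are
drawn as stationary Gaussian processes directly from the implied
correlation matrix, which makes the population Pearson structure exactly
the one requested; an optional carrier band passes the correlated noise
through the band filter so banded analyses see realistic spectral content
(linear filtering applied identically to all channels preserves the
cross-channel correlations).

Geometric fixtures (circle, sphere, square, line, random) have known
homology and serve as ground truth for the filtration and persistence
stages: a circle has one connected component and one loop, a sphere one
component and one void, the unit square's Vietoris-Rips loop is born at
edge length 1 and filled at the diagonal sqrt(2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bands import BandDefinition, band_filter
from .embed import PointCloud
from .recording import MultichannelRecording

__all__ = [
    "CohortSpec",
    "GeometricFixture",
    "generate_cohort_recording",
    "generate_fixture",
    "implied_correlation",
]

FIXTURE_NAMES = ("circle", "sphere", "square", "line", "random")


@dataclass
class CohortSpec:
    """Recipe for one cohort's recordings.

    ``block_partition`` lists disjoint channel-index sets covering all
    channels; channels correlate at ``within_block_r`` inside a block and
    ``between_block_r`` across blocks.  ``noise_sd`` scales the per-channel
    signal amplitude (Pearson correlations are scale-free, so it does not
    affect the network).
    """

    n_channels: int = 60
    n_samples: int = 2000
    sampling_rate: float = 250.0
    block_partition: list[list[int]] = field(default_factory=list)
    within_block_r: float = 0.0
    between_block_r: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.block_partition:
            self.block_partition = [list(range(self.n_channels))]
        flat = sorted(i for block in self.block_partition for i in block)
        if flat != list(range(self.n_channels)):
            raise ValueError(
                "block_partition must cover every channel index exactly once")
        for r, name in ((self.within_block_r, "within_block_r"),
                        (self.between_block_r, "between_block_r")):
            if not -1 < r < 1:
                raise ValueError(f"{name} must lie in (-1, 1), got {r}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        corr = implied_correlation(self)
        lam_min = float(np.linalg.eigvalsh(corr)[0])
        if lam_min < -1e-10:
            raise ValueError(
                "implied correlation matrix is not positive semidefinite "
                f"(min eigenvalue {lam_min:.3g}) for within_block_r="
                f"{self.within_block_r}, between_block_r={self.between_block_r}, "
                f"blocks of sizes {[len(b) for b in self.block_partition]}"
            )


def implied_correlation(spec: CohortSpec) -> np.ndarray:
    """Population correlation matrix the spec implies."""
    n = spec.n_channels
    corr = np.full((n, n), spec.between_block_r)
    for block in spec.block_partition:
        ix = np.ix_(block, block)
        corr[ix] = spec.within_block_r
    np.fill_diagonal(corr, 1.0)
    return corr


def generate_cohort_recording(
    spec: CohortSpec,
    carrier_band: BandDefinition | None = None,
) -> MultichannelRecording:
    """Draw one recording with the spec's exact population Pearson structure.

    The same spec and seed always produce bit-identical output.  With
    ``carrier_band`` set, the correlated white noise is band-passed so its
    spectrum is concentrated in that band (correlations are unchanged up to
    sampling noise, since every channel passes through the same filter).
    """
    corr = implied_correlation(spec)
    lam, q = np.linalg.eigh(corr)
    root = q @ np.diag(np.sqrt(np.clip(lam, 0.0, None)))
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((spec.n_channels, spec.n_samples))
    data = spec.noise_sd * (root @ z)
    labels = [f"ch{i:02d}" for i in range(spec.n_channels)]
    rec = MultichannelRecording(data, spec.sampling_rate, labels)
    if carrier_band is not None and not carrier_band.is_full:
        rec = band_filter(rec, carrier_band)
        rec.band = None  # carrier shaping, not an analysis band selection
    return rec


@dataclass
class GeometricFixture:
    """Recipe for a small point cloud with known homology."""

    name: str
    n_points: int = 20
    ambient_dim: int | None = None
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in FIXTURE_NAMES:
            raise ValueError(
                f"unknown fixture {self.name!r}; supported: {', '.join(FIXTURE_NAMES)}")
        if self.n_points < 1:
            raise ValueError("n_points must be at least 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def generate_fixture(fix: GeometricFixture) -> PointCloud:
    """Materialise a fixture as coordinates.

    * ``circle`` — n points evenly spaced on the unit circle;
    * ``sphere`` — Fibonacci lattice on the unit sphere (deterministic,
      quasi-uniform);
    * ``square`` — the 4 unit-square corners (n_points ignored);
    * ``line`` — collinear points at 0, 1, ..., n-1 on the first axis;
    * ``random`` — uniform draws from the unit cube.

    Gaussian coordinate noise of scale ``noise_sd`` is added afterwards;
    the same seed reproduces the same cloud.  A single requested point is
    always the origin.
    """
    rng = np.random.default_rng(fix.seed)
    n = fix.n_points
    base_dim = {"circle": 2, "sphere": 3, "square": 2, "line": 1, "random": 3}[fix.name]
    if n == 1:
        coords = np.zeros((1, base_dim))
    elif fix.name == "circle":
        angles = 2 * math.pi * np.arange(n) / n
        coords = np.column_stack([np.cos(angles), np.sin(angles)])
    elif fix.name == "sphere":
        coords = _fibonacci_sphere(n)
    elif fix.name == "square":
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    elif fix.name == "line":
        coords = np.arange(n, dtype=float)[:, None]
    else:  # random
        coords = rng.uniform(size=(n, base_dim))
    if fix.noise_sd > 0:
        coords = coords + rng.normal(scale=fix.noise_sd, size=coords.shape)
    if fix.ambient_dim is not None:
        if fix.ambient_dim < coords.shape[1]:
            raise ValueError(
                f"ambient_dim {fix.ambient_dim} below intrinsic dimension "
                f"{coords.shape[1]} of {fix.name}")
        pad = np.zeros((coords.shape[0], fix.ambient_dim - coords.shape[1]))
        coords = np.hstack([coords, pad])
    return PointCloud(coords, source_note=f"fixture {fix.name} (seed {fix.seed})")


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform deterministic sphere sampling via the golden angle."""
    k = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z ** 2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
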