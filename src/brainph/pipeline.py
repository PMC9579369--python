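"""End-to-end orchestration: recording to stability tables.

For each requested band the pipeline runs

    recording -> band filter -> Pearson correlation -> reciprocal distance
    -> ISOMAP point cloud -> Vietoris-Rips filtration -> persistence diagram

and, when two cohorts are supplied, closes with a per-band table of
bottleneck (exact and approximate) and Wasserstein distances between the
cohort diagrams.  Every artefact is written as plain text under the output
directory together with a JSON manifest recording all parameters and
seeds, so any output file can be regenerated from the manifest alone.

The maximum filtration threshold defaults to the largest inter-node
distance of each band's own distance matrix — the full-scale sweep that
removes the need to choose a binarisation threshold — and can be pinned to
a fixed value for cross-run comparability.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import bands as bands_mod
from .embed import isomap, write_point_cloud
from .netbuild import (
    max_threshold,
    pearson_matrix,
    reciprocal_distance,
    write_edge_weights,
)
from .persist import PersistenceDiagram, persistent_homology
from .plots import plot_barcode, plot_persistence_diagram
from .recording import MultichannelRecording, read_delimited, read_edf
from .rips import count_by_dimension, rips_filtration
from .stability import compare_groups

__all__ = ["PipelineConfig", "run_pipeline", "read_recording"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of one run; defaults follow the concluded analysis settings
    (max dimension 2, 20 filtering steps, full-scale threshold, bottleneck
    accuracy 0.01, 1-Wasserstein)."""

    bands: list[str] = field(default_factory=lambda: ["full"])
    reciprocal_cap: float = 1000.0
    isomap_k: int = 7
    isomap_dim: int | None = None
    max_dim: int = 2
    eps_max: float | None = None        # None = per-band maximum distance
    fs: int | None = 20
    min_length: float = 0.0
    bottleneck_e: float = 0.01
    wasserstein_p: float = 1.0
    seed: int = 0
    make_plots: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)


def read_recording(path: str | Path, fmt: str | None = None,
                   sampling_rate: float | None = None) -> MultichannelRecording:
    """Load a recording from EDF or a delimited channels x samples matrix.

    ``fmt`` is inferred from the suffix when omitted (``.edf`` vs text).
    Delimited matrices without a metadata header need ``sampling_rate``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if fmt == "edf":
        return read_edf(path)
    if fmt == "delimited":
        return read_delimited(path, sampling_rate=sampling_rate)
    raise ValueError(f"unknown recording format {fmt!r}; use 'edf' or 'delimited'")


def _resolve_bands(names: list[str]) -> list[bands_mod.BandDefinition]:
    known = {b.name: b for b in bands_mod.standard_bands()}
    out = []
    for name in names:
        if name not in known:
            raise ValueError(f"unknown band {name!r}; known: {sorted(known)}")
        out.append(known[name])
    return out


def _process_cohort(
    rec: MultichannelRecording,
    cohort: str,
    cfg: PipelineConfig,
    outdir: Path,
) -> tuple[dict[str, PersistenceDiagram], dict]:
    diagrams: dict[str, PersistenceDiagram] = {}
    stage_log: dict = {}
    for band in _resolve_bands(cfg.bands):
        t0 = time.perf_counter()
        prefix = outdir / f"{cohort}_{band.name}"
        banded = bands_mod.band_filter(rec, band)
        corr = pearson_matrix(banded)
        corr.to_text(prefix.with_name(prefix.name + "_correlation.tsv"))
        dist = reciprocal_distance(corr, cap=cfg.reciprocal_cap)
        dist.to_text(prefix.with_name(prefix.name + "_distance.tsv"))
        edges = write_edge_weights(dist)
        edges.to_text(prefix.with_name(prefix.name + "_edges.txt"))
        cloud, report = isomap(dist, k=cfg.isomap_k, target_dim=cfg.isomap_dim,
                               auto_connect=True)
        write_point_cloud(cloud, prefix.with_name(prefix.name + "_pointcloud.txt"))
        eps_max = cfg.eps_max if cfg.eps_max is not None else max_threshold(dist)
        filt = rips_filtration(dist, max_dim=cfg.max_dim, eps_max=eps_max, fs=cfg.fs)
        counts = count_by_dimension(filt)
        diag = persistent_homology(filt, validate=False)
        diag.to_text(prefix.with_name(prefix.name + "_diagram.tsv"))
        if cfg.make_plots:
            plot_barcode(diag, prefix.with_name(prefix.name + "_barcode.png"))
            plot_persistence_diagram(
                diag, prefix.with_name(prefix.name + "_diagram.png"))
        diagrams[band.name] = diag
        stage_log[f"{cohort}/{band.name}"] = {
            "input_sha1": hashlib.sha1(rec.data.tobytes()).hexdigest()[:12],
            "eps_max": eps_max,
            "isomap_dim": report.chosen_dim,
            "simplex_counts": {str(k): v for k, v in counts.items()},
            "n_intervals": len(diag),
            "wall_time_s": round(time.perf_counter() - t0, 3),
        }
        log.info("stage %s/%s done in %.2fs (eps_max=%.4g, %d intervals)",
                 cohort, band.name, stage_log[f"{cohort}/{band.name}"]["wall_time_s"],
                 eps_max, len(diag))
    return diagrams, stage_log


def run_pipeline(
    cfg: PipelineConfig,
    recording_a: MultichannelRecording,
    recording_b: MultichannelRecording | None = None,
    outdir: str | Path = "brainph_out",
    cohort_names: tuple[str, str] = ("cohortA", "cohortB"),
) -> dict:
    """Run all stages; returns a manifest dict (also written as JSON).

    With one recording the run stops after the per-band diagrams; with two,
    a distance table between the cohorts' diagrams is added
    (``distance_table.tsv``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg.to_dict(), "stages": {}, "outputs": []}
    try:
        diagrams_a, log_a = _process_cohort(recording_a, cohort_names[0], cfg, outdir)
        manifest["stages"].update(log_a)
        if recording_b is not None:
            diagrams_b, log_b = _process_cohort(
                recording_b, cohort_names[1], cfg, outdir)
            manifest["stages"].update(log_b)
            dims = tuple(range(min(cfg.max_dim, 2)))  # Dim0/Dim1 stability table
            table = compare_groups(
                diagrams_a, diagrams_b, dims=dims,
                p_orders=(cfg.wasserstein_p,), e=cfg.bottleneck_e)
            table_path = outdir / "distance_table.tsv"
            table.to_csv(table_path, sep="\t")
            manifest["distance_table"] = {
                c: dict(zip(table.index, table[c])) for c in table.columns}
    except Exception as exc:
        manifest["failed_stage"] = f"{type(exc).__name__}: {exc}"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    manifest["outputs"] = sorted(p.name for p in outdir.iterdir())
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
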