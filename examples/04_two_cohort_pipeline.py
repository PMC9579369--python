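"""Full two-cohort pipeline: recordings to a stability distance table.

Two synthetic cohorts share block layout but differ in within-block
coupling (0.7 vs 0.4) — a connectivity difference like the one the method
is designed to detect.  The pipeline writes, per band and cohort, the
correlation/distance matrices, edge list, ISOMAP point cloud, persistence
diagram and plots, plus a distance table comparing the cohorts.
"""

from pathlib import Path

from brainph import (
    CohortSpec, PipelineConfig, generate_cohort_recording, run_pipeline,
)

partition = [list(range(k * 10, (k + 1) * 10)) for k in range(6)]


def cohort(within, seed):
    return generate_cohort_recording(CohortSpec(
        n_channels=60, n_samples=2000, sampling_rate=250.0,
        block_partition=partition, within_block_r=within,
        between_block_r=0.25, seed=seed))


out = Path("brainph_out")
cfg = PipelineConfig(bands=["full"], max_dim=2, fs=20)
manifest = run_pipeline(cfg, cohort(0.7, 11), cohort(0.4, 22), outdir=out)

print(f"wrote {len(manifest['outputs'])} files to {out}/")
stage = manifest["stages"]["cohortA/full"]
print(f"cohort A: eps_max {stage['eps_max']:.3f}, ISOMAP dim {stage['isomap_dim']}, "
      f"{stage['simplex_counts']['total']} simplices, {stage['n_intervals']} intervals")
table = manifest["distance_table"]
print(f"between-cohort Dim0 bottleneck: {table['dim0_bottleneck']['full']:.3f}")
print(f"between-cohort Dim0 Wasserstein: {table['dim0_wasserstein_p1']['full']:.3f}")
print("a larger distance means the cohorts' multi-scale network topology differs;")
print("compare against a split-half within-cohort distance to judge the effect.")
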