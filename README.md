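# brainph

Threshold-free analysis of EEG functional-connectivity networks with
persistent homology.

## The problem

Building a brain network from multichannel EEG usually ends with a hard
choice: the correlation matrix between electrodes must be binarised at
some threshold, and the resulting graph topology depends heavily on which
threshold is picked. There is no agreed criterion for picking one.

`brainph` sidesteps the choice by analysing the network at *every* scale
at once. Electrodes become points in a metric space where the distance
between nodes *i* and *j* is the reciprocal of their Pearson correlation
magnitude, `d_ij = min(1/|r_ij|, cap)`. Sweeping a scale parameter ε from
0 to the largest inter-node distance produces a nested family of
Vietoris–Rips complexes — the complex at scale ε contains a simplex on
every vertex set whose pairwise distances are all ≤ ε. Persistent
homology tracks the topological features of this family: each connected
component (Betti dimension 0), loop (dimension 1) and void (dimension 2)
is born at some scale ε_birth and dies at some ε_death. The multiset of
intervals [ε_birth, ε_death) is the **persistence diagram** (equivalently
the barcode); long intervals are structure, short ones noise.

Two diagrams X, Y are compared with matching-based distances, with
unmatched points projected to the diagonal:

* **bottleneck distance** `W∞(X,Y) = inf_φ sup_x d∞(x, φ(x))` — the
  largest single discrepancy (robust);
* **p-Wasserstein distance** `Wp(X,Y) = inf_φ (Σ_x d∞(x, φ(x))^p)^{1/p}`
  — the total discrepancy (sensitive).

The bottleneck distance is *stable*: a small perturbation of the data
moves the diagram by at most the perturbation of the distance matrix, so
diagram distances are a principled way to compare groups (e.g. patients
vs controls) without ever binarising.

## What the package provides

| module | role |
|---|---|
| `brainph.synthetic` | block-correlated 60-channel recordings and geometric fixtures with known homology |
| `brainph.recording` | channels × samples container; delimited-text and EDF I/O |
| `brainph.bands` | zero-phase decomposition into θ (4–7), α (7–14), β₁ (14–20), β₂ (20–30), γ (30–40 Hz) + full band |
| `brainph.netbuild` | Pearson matrix, reciprocal distances, edge-weight lists, density-thresholded binary views |
| `brainph.embed` | ISOMAP (k-NN graph → geodesics → classical MDS) to point-cloud coordinates |
| `brainph.rips` | Vietoris–Rips filtration, exact or snapped to an Fs-step grid |
| `brainph.persist` | persistent homology over GF(2) by twist column reduction + independent rank-based oracle |
| `brainph.stability` | bottleneck (exact / accuracy-e) and p-Wasserstein distances, group tables |
| `brainph.pipeline` | end-to-end orchestration with a JSON run manifest |
| `brainph.cli` | thin `brainph` command (`generate`, `build-net`, `embed`, `rips`, `persist`, `compare`, `run`) |

## Worked example

`examples/02_point_cloud_homology.py` computes the homology of clouds
whose topology is known in closed form:

```
circle loop: born 0.3129 (adjacent chord 2*sin(pi/20) = 0.3129), dies 1.7820
Betti numbers at mid-scale eps=1: {0: 1, 1: 1} (one component, one loop)
square loop interval: [1.0000, 1.4142) = [1, sqrt2); its length 0.4142 is the bar drawn in a barcode
```

The circle's single Dim1 bar is born exactly when adjacent points connect
(chord length 2·sin(π/20)) and at mid-scale the Betti numbers are those of
a circle, β₀ = β₁ = 1. The square's loop appears with its four unit sides
and is filled by the √2 diagonals.

`examples/04_two_cohort_pipeline.py` runs the full pipeline on two
synthetic cohorts that differ only in within-block coupling (0.7 vs 0.4):

```
cohort A: eps_max 5.214, ISOMAP dim 39, 36050 simplices, 62 intervals
between-cohort Dim0 bottleneck: 0.963
between-cohort Dim0 Wasserstein: 52.865
```

The between-cohort bottleneck distance (0.96) is well above the
within-cohort split-half distance (≈0.5 for these conditions), i.e. the
multi-scale topology separates the groups. All outputs (matrices, edge
lists, point clouds, diagrams, barcode/diagram plots, the distance table
and a manifest with every parameter and seed) land in `brainph_out/`.

The same pipeline runs from the shell:

```bash
brainph generate --n-channels 60 --seed 1 cohortA.tsv
brainph run --bands full,alpha --out results_dir cohortA.tsv cohortB.tsv
```

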