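# Methods

## Model overview

The package implements a multi-scale ("full-scale") brain-network
analysis: instead of binarising a functional-connectivity matrix at one
threshold, the network is examined across the entire range of connection
scales and summarised by the persistent homology of a Vietoris–Rips
filtration.

Stages, in order:

1. **Band decomposition.** Each channel is band-passed into θ (4–7 Hz),
   α (7–14), β₁ (14–20), β₂ (20–30), γ (30–40), plus an unfiltered "full"
   band, so every later quantity exists per band.
2. **Metric space.** The sample Pearson correlation r_ij between channel
   signals defines the node distance d_ij = min(1/|r_ij|, cap). Strong
   (anti-)correlation ⇒ short distance; a cap keeps distances finite when
   r ≈ 0.
3. **Point cloud.** ISOMAP embeds the distance matrix into coordinates:
   symmetric k-nearest-neighbour graph, exact all-pairs shortest paths,
   classical MDS of the geodesic matrix.
4. **Filtration.** The Vietoris–Rips complex at scale ε contains a simplex
   whenever all pairwise distances among its vertices are ≤ ε. ε sweeps
   [0, ε_max] with ε_max defaulting to the maximum inter-node distance, so
   the sweep is genuinely full-scale (the final complex is complete).
5. **Persistence.** Homology over GF(2) tracked along the filtration
   yields (dimension, birth, death) intervals; dimension 0 = components,
   1 = loops, 2 = voids.
6. **Stability / group comparison.** Diagrams of two groups are compared
   per band and dimension with the bottleneck distance (exact and at
   accuracy e) and the p-Wasserstein distance.

## Assumptions

* Input recordings are already re-referenced and artifact-cleaned;
  upstream preprocessing is out of scope.
* Connectivity is undirected and instantaneous (Pearson); lagged or
  directed measures are out of scope.
* Correlation magnitude is what matters: anti-correlated channels count
  as coupled. This is required for distances to be positive and treats
  inhibition as connectivity.
* The homology coefficient field is GF(2), the standard choice for
  persistence (signs never need tracking).

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| reciprocal cap | 1000 | distance | bounds 1/|r| when r ≈ 0; pairs at the cap are "uncoupled". Only affects scales beyond any structure of interest. |
| ISOMAP k | 7 | neighbours | smallest neighbourhood that usually stays connected; the symmetric union rule (edge kept if either endpoint selects it) maximises connectivity at small k. The pipeline raises k to the minimal connecting value when the graph is disconnected, and logs it. |
| embedding dimension | auto | — | keep eigen-components with λ > 1e-8·λ_max, capped at n−1. Mirrors a data-driven dimension choice; on 60-node synthetic runs this lands in the mid-30s. |
| max_dim | 2 | simplex dim | homology is reported for dimensions 0..max_dim−1, i.e. components and loops by default; build max_dim = 3 to resolve voids. |
| ε_max | auto | distance | maximum off-diagonal distance of the band's own matrix (full-scale sweep); can be pinned for cross-run comparability. |
| Fs | 20 | steps | number of grid subdivisions of [0, ε_max]; entry values snap *upward* to the grid so a simplex never appears before it exists. Fs→∞ converges to the exact filtration (error < ε_max/Fs, tested). |
| bottleneck e | 0.01 | distance | approximate-mode bracket width; returned value is within e of exact. e=0 requests the exact candidate-set search. |
| Wasserstein p | 1 | — | total-discrepancy summary; any p ≥ 1 is supported. |
| min_length | 0 | distance | bar-length cutoff separating persistent features from noise in `classify_intervals`. |

## Numerical choices

* **Band filter.** Butterworth band-pass of order 6 per direction applied
  forward and backward (`sosfiltfilt`, zero phase) with point-reflection
  end padding. Measured steady-state response: ≥ 99.4 % amplitude at the
  band's geometric centre, ≤ 0.2 % one octave outside. Note that the
  *full-record* RMS of a filtered out-of-band tone can be a few percent:
  truncating a tone at the record edges leaks genuinely in-band energy
  that no linear filter can remove. Filter-quality claims therefore refer
  to steady-state (record-centre) amplitude.
* **Rips construction** by incremental expansion over lower-neighbour
  sets; equivalence with brute-force subset enumeration is tested. Ties
  are ordered deterministically by (value, dimension, vertex tuple).
* **Persistence** by column reduction in filtration order with the
  dimension-descending clearing ("twist") optimisation; columns are
  Python-integer bitsets. Zero-length intervals are discarded (invisible
  in barcodes). Classes in the filtration's top simplex dimension are not
  reported, since their deaths would need cofaces one dimension higher.
* **Independent oracle.** `brute_force_oracle` recomputes diagrams from
  Gaussian-elimination ranks of boundary submatrices at every pair of
  filtration values (persistent Betti numbers + inclusion–exclusion). It
  shares no code with the reduction and is the cross-check in the tests.
* **Bottleneck distance.** Feasibility of "all points matched within t"
  is a perfect-matching test on the diagonal-augmented bipartite graph
  (scipy's maximum bipartite matching). Exact mode binary-searches the
  sorted candidate costs (the optimum is always one); approximate mode
  bisects a real bracket to width ≤ e and returns the midpoint.
* **Wasserstein** is solved exactly as a square assignment problem on the
  diagonal-augmented cost matrix (Hungarian algorithm).
* **Ground metric** between diagram points is the sup-norm on the
  (birth, death) plane — the metric under which the stability theorem
  holds in its standard form; diagonal projection costs (death−birth)/2.
  An L2 option exists but is not the default.
* **Essential intervals** (death = ∞) are excluded from diagram distances
  by default; ∞-vs-∞ matching has no canonical cost. A truncate-to-ε_max
  option supports stability experiments, where both diagrams share ε_max.
* **Degenerate inputs** are rejected with named offenders: zero-variance
  channels, non-PSD synthetic correlation targets, disconnected k-NN
  graphs (reporting component count and the minimal connecting k),
  closure-violating filtrations (reporting the missing/late face).

## The synthetic-data generator

Clinical task EEG is rarely shareable, so the study conditions are
emulated. Channels are partitioned into blocks; signals are stationary
Gaussian processes drawn from the implied block-correlation matrix
(within-block r inside, between-block r across), which makes the
*population* Pearson structure exactly the requested one and gives exact
seeded reproducibility. An optional carrier band passes the correlated
noise through the band filter; since every channel passes the identical
linear filter, cross-channel correlations are preserved while the
spectrum concentrates in the band.

The canonical two-cohort study generated by the tests and the acceptance
script uses 60 channels in six blocks of ten, 2000 samples at 250 Hz,
between-block r = 0.25, and within-block r = 0.7 (cohort A) vs 0.4
(cohort B). These values were fixed once: 0.25 between-block coupling
keeps the weakest sample correlations near 0.15–0.25 so the automatic
ε_max lands in the realistic 4–7 range for reciprocal-correlation
distances, and the 0.7-vs-0.4 contrast is a large, unambiguous
connectivity difference suitable for a desk-scale separation check.

What the generator does **not** emulate: volume conduction, non-Gaussian
and non-stationary dynamics, 1/f spectra, artifacts, per-subject
variability (a cohort is one recording, i.e. a group-level matrix).
Passing tests therefore demonstrate correctness of the machinery and the
qualitative group-separation behaviour, not clinical effect sizes.

Geometric fixtures provide known homology for the persistence stages:
circle (β₀ = β₁ = 1), Fibonacci-lattice sphere (β₀ = β₂ = 1), the unit
square (Rips loop exactly [1, √2)), collinear points and uniform random
clouds. Sphere sampling is a deterministic Fibonacci lattice, so fixture
homology does not depend on a random draw.

## Problem sizes

Tests and the acceptance script run at sizes chosen for fast, exact
verification: oracle cross-checks on ≤ 8-point clouds (where the rank
oracle is exact and cheap), fixtures of 4–24 points, diagrams of ≤ 30
points for the metric suite, and the 60-channel two-cohort study
(≈ 36 000 simplices per filtration). The implementation itself handles
hundreds of nodes; the brute-force oracle deliberately refuses inputs
above 2000 simplices because it exists for verification, not production.

## Known limitations

* The reduction is pure Python; very dense filtrations (≫ 10⁵ simplices)
  will be slow compared to compiled persistent-homology engines.
* Only Vietoris–Rips complexes are built (no Čech/alpha/witness).
* No statistical inference on diagram distances (no permutation nulls);
  the distances are descriptive.
* Representative cycles, cohomology and vectorised summaries
  (landscapes, images, Betti curves, persistence entropy) are out of
  scope.
* EDF export writes a single data record with 16-bit quantisation —
  adequate for interchange and round-trip tests, not a full-featured
  EDF+ implementation.
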