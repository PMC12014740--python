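# Methods

This note documents the models, estimators, numerical choices, and
validation studies implemented in `braindyn`, and what the passing tests do
and do not demonstrate about real data.

## Dynamic connectivity

Parcellated BOLD series (time × region, repetition time `tr_seconds`) are
band-pass filtered per region with a zero-phase 4th-order Butterworth filter
(default band 0.01–0.08 Hz, applied forward–backward so no phase shift is
introduced; output length equals input length). Filtering precedes
windowing. Dynamic connectivity is the stack of Pearson correlation matrices
over rectangular sliding windows (defaults: 22 TR length, 1 TR step), so a
series of `T` time points yields `T − 21` windows. Windows are untapered; a
zero-variance region in any window is an error, not a silent NaN.

The synthetic generator (below) produces series whose regime structure lives
in the spatial covariance with temporally independent (optionally AR(1))
samples; synthetic validation studies therefore window the generated series
directly, since the generator emulates the *already cleaned and band-limited*
signal the pipeline receives. Filtering white-spectrum synthetic noise to a
0.01–0.08 Hz band would only lower the effective samples per window without
making the data more realistic.

## Signed community structure and cartography

Each window's correlation matrix is a fully signed graph (diagonal zeroed).
Modularity uses the asymmetric signed form: positive within-module weight is
rewarded relative to a per-sign configuration null `e±ij = s±i s±j / v±`
(full-matrix sums, diagonal null terms included), and negative within-module
weight is penalized with the damped prefactor `1/(v+ + v−)`. The resolution
`γ` (default 1) multiplies both null terms.

Partitions are found by a Louvain scheme on this objective:

* greedy node moves from a given starting partition, best-improvement with
  lowest-index tie-break, under a seeded random node order (numba-compiled);
  a sweep terminates when a full pass improves `Q` by less than `1e-7` — on
  noisy window graphs near-tied assignments otherwise oscillate at float
  precision indefinitely;
* aggregation into module super-nodes (self-loops carried) and repeat;
* node-level refinement: after the levels converge, fresh node moves on the
  original graph warm-started from the partition, alternating with
  re-aggregation until stable (aggregation alone can lock single nodes into
  early merges).

The consensus over `repetitions` runs (default 100) forms the co-assignment
agreement matrix, zeroes entries below τ = 0.5, and re-clusters it with the
same algorithm until all runs coincide (bounded rounds, error on
non-convergence). Because near-tied runs can produce a consensus partition
that scores below one of its constituents, the returned partition is never
`Q`-dominated by a first-round run: if it is, the best run is returned
instead. This guarantee is what lets consensus track the exhaustive-search
optimum on small dense signed graphs (validated against all 877 partitions
of 7 nodes).

Node roles use positive weights only: participation
`B_i = 1 − Σ_s (K_is/K_i)²` (zero-strength nodes get `B = 0`) and
within-module z-score with population SD (modules with zero SD, including
singletons, get `W = 0`). Per window, the node (B, W) pairs are binned into
a joint histogram — default grid 50 × 50 over `B ∈ [0,1] × W ∈ [−5,5]`,
out-of-range `W` clipped into the end bins so mass always equals the node
count. The validation studies use a 10 × 10 grid: with ~100 regions per
window a 2500-bin histogram is almost empty and correlation distances
between profiles become noise-dominated.

## States and dynamics

Profiles are clustered per subject with k-means under correlation distance
`d = 1 − corr`, implemented by standardizing each flattened profile to zero
mean and unit norm (then `d = ||u − v||²/2` and Lloyd iterations apply);
best of `restarts` random initializations (default 300; restarts that empty
a cluster are redrawn). Inputs whose profiles are all perfectly correlated
are flagged degenerate and returned as a single cluster. The cluster whose
windows have the higher mean participation coefficient is labeled
*integrated* (exact ties break toward the lower cluster index, with a
warning). State centroids average connectivity on the Fisher-z scale,
`tanh(mean(atanh r))`, with `r` clipped to ±(1 − 1e−7). Silhouette scores
over k = 2..7 use the same correlation distance; points in singleton
clusters are excluded from the mean with a warning.

Dynamic measures of the binary state sequence: fraction time; dwell time
(mean run length, window units; multiply by `tr_seconds` for seconds); total
transitions; sample entropy (template length m = 2, tolerance 0.2 × SD,
Chebyshev distance; constant sequences return 0, undefined ratios return NaN
with a warning); and Lempel–Ziv complexity (LZ76 exhaustive-history parsing,
phrase count reported raw and normalized by `n / log2 n`). Entropy and
complexity are computed on the binary sequence directly.

## Group statistics

Edgewise tests operate on Fisher-z upper-triangle centroid edges. The group
effect is the partial F given an intercept and the nuisance covariates age,
sex, education, and mean framewise displacement (rank-deficient designs are
rejected naming the columns). NBS forms connected components among edges
with `p < 0.05` (0.01 as a sensitivity setting) and compares the observed
component sizes (edge-count extent) with the permutation distribution of the
maximum null component size; permutation follows Freedman–Lane (residuals of
the nuisance-only model are permuted and added back to the nuisance fit),
and `p = (1 + #{null ≥ obs}) / (1 + n_perm)`. The signed difference matrix
reported alongside is `tanh(mean z_case − mean z_control)` per edge.

Graph metrics use the positive part with edge length `1/weight` for all
path-based quantities; negative weights enter only negative strength, signed
modularity, and functional complexity (absolute values). Local efficiency is
the mean over nodes of the global efficiency of the neighbor-induced
subgraph. Functional complexity histograms `|w| ≥ τ` into 20 equal bins over
`[τ, 1]` and reports `1 − D/D_max` (`D` the L1 distance to uniform); default
thresholds τ ∈ {0, 0.1, 0.2, 0.3}. Clustering is Onnela's geometric-mean
form; characteristic path length averages finite distances only, while
disconnected pairs contribute zero to efficiency. Null ensembles for
nC/nL/SW preserve the positive-part degree sequence (Maslov–Sneppen double
edge swaps; saturated topologies such as complete graphs keep their edges)
and reshuffle the weight multiset. Betweenness is unnormalized Brandes on
the same lengths, averaged over nodes.

Map associations use Spearman's ρ with average ranks. Cortical significance
comes from spin permutations: a uniform random rotation (mirrored between
hemispheres) is applied to parcel centroids about each hemisphere's centre,
and parcels are reassigned by minimum-total-distance one-to-one matching
(Hungarian algorithm), so every null map is a permutation of the data;
rotations that reproduce the identity permutation are redrawn. Subcortical
values are shuffled within hemisphere; whole-brain tests permute both
components jointly per iteration. Optimal matching matters: greedy matching
partially scrambles the spun map's autocorrelation, which measurably narrows
the null and inflates false positives. All permutation p-values count ties
at float precision as exceedances. Metric-level group tests reuse the
partial-F engine with BH-FDR across metrics × states; consumption-pattern
couplings are Pearson partial correlations (t-based p, df = n − k − 2),
reported uncorrected and flagged exploratory. Residual normality is checked
with Shapiro–Wilk on covariate-adjusted residuals.

## Synthetic cohorts

The generator plants exactly the structure the pipeline assumes:

* **Regimes.** A segregated correlation template (within-module 0.6,
  between-module 0.0 by default) and an integrated template with uniform
  off-diagonal correlation (0.15 by default). Both are validated positive
  definite (smallest eigenvalue reported otherwise). Defaults: 100 regions
  in 5 equal modules. The integrated coupling is deliberately weak: strong
  uniform correlation makes the detected partition collapse to a single
  module, where participation is identically zero and the state labeling
  convention inverts; weak global coupling keeps detected modules dispersed
  and participation high, which is the topology the integrated state is
  meant to represent. The 100-region scale mirrors standard parcellations;
  histograms over 20 regions proved too sparse to cluster reliably.
* **Dynamics.** A two-state Markov chain per TR, parameterized as a
  reversible exchange process: switching rate `r = 2(1 − stay_probability)`,
  `P(S→I) = r·π_I`, `P(I→S) = r·(1 − π_I)`, so the stationary integrated
  occupancy is exactly `π_I` and at occupancy 0.5 both regimes keep
  `stay_probability`. Regime changes apply instantaneously at TR boundaries;
  given the active regime, samples are independent multivariate normals
  (optional AR(1) with preserved marginal covariance).
* **Group effect.** A correlation offset added on chosen edges for case
  subjects (both regime templates), with Higham-style nearest-positive-
  definite repair and re-normalization to unit diagonal when the offset
  breaks positive definiteness; offsets leaving (−1, 1) are rejected.
* **Covariates.** age ~ U(18, 50), sex ~ Bernoulli(0.83 male),
  education ~ U(6, 20) years, mean FD ~ U(0.05, 0.4) mm; case subjects also
  draw years of use ~ N(10.24, 6.81²) (floored at 0.5) and age of onset ~
  N(21.13, 5.80²) (clipped to [12, age]).
* **Atlas and maps.** The synthetic atlas models each hemisphere as a full
  Fibonacci-lattice sphere (mirrored, offset on x), as in surface-based
  registration; subcortical parcels carry hemisphere labels only. Density
  maps are Gaussian fields with a squared-exponential kernel in chordal
  distance (monotone in great-circle distance; chordal distance keeps the
  kernel positive definite on the sphere), with independent subcortical
  values per hemisphere.
* **Connectivity-level cohorts.** For calibration and power studies of the
  group-statistics stages, `generate_connectivity_cohort` draws per-subject
  centroid matrices directly on the Fisher-z scale with a standardized
  (Cohen's d) group shift on planted edges — orders of magnitude cheaper
  than simulating time series when thousands of NBS runs are needed.

What the generator does **not** emulate: hemodynamics, scanner noise,
motion artifacts, temporal autocorrelation of real BOLD (beyond optional
AR(1)), spatially heterogeneous module sizes, and covariate–connectivity
confounding (covariates are independent of connectivity unless planted).
Passing tests therefore demonstrate the statistical machinery is correct and
calibrated under its own assumptions, not that those assumptions hold in any
real dataset.

## Validation studies and problem sizes

All studies live in `braindyn.validation` and are run both by the test suite
and by `scripts/acceptance.py`; study-scale analysis settings are 10
consensus repetitions per window, 10 × 10 profile bins, and 100 k-means
restarts (production defaults are 100 / 50 × 50 / 300).

* **Oracle agreement.** Every statistic (signed Q, B, W, efficiencies,
  clustering, path length, betweenness, Spearman, BH, partial r, nested F)
  is compared with an independent brute-force implementation — explicit
  double/triple loops, Floyd–Warshall, exhaustive shortest-path enumeration,
  textbook rank and step-up formulas — on a 100-graph random suite (≤ 10
  nodes), agreement ≤ 1e−10.
* **Consensus optimality.** On 50 random dense signed 7-node graphs × 20
  seeds, consensus Louvain (100 repetitions) attains ≥ 0.95 of the
  exhaustive-search optimum (877 partitions) in ≥ 95% of runs.
* **State recovery.** 20 + 20 subjects, 300 TR, occupancy 0.64, stay 0.9.
  With a 22-TR window and per-TR stay 0.9 the mean regime dwell times
  (≈ 13.9 / 7.8 TR) are *shorter than the window*, so most windows mix both
  regimes. Windows lying entirely within one regime are recovered at ≈ 0.9
  accuracy; accuracy against each window's majority regime plateaus near
  0.75 (an oracle thresholding the true mixture fraction cannot exceed
  ≈ 0.8 under this dwell/window ratio), the estimated fraction time sits
  below the TR-level occupancy because the two-cluster boundary splits the
  mixture continuum near its mass median, and the silhouette scan
  occasionally prefers k = 3 — mixture windows form a real third profile
  class. These are properties of the simulated dynamics, not of the
  estimator; with dwell times long relative to the window the same pipeline
  recovers states nearly perfectly.
* **NBS calibration and power.** 100 null cohorts (15 regions, 20 + 20,
  200 permutations): empirical FWE within the exact binomial 95% interval
  of 0.05. Power: a planted 10-edge component spanning two modules
  (d = 1.2, n = 40, 500 permutations, 50 replicates): detection ≥ 80% and
  mean edge Jaccard vs truth ≥ 0.5.
* **Permutation validity.** Spin p-values under 200 independent smooth map
  pairs (80 parcels, length-scale 0.5, 1000 shared permutations) are
  uniform (KS); hemisphere-shuffle likewise; on correlated smooth pairs the
  spin p exceeds the naive unstructured-permutation p on average.
* **Direction of effect.** A positive offset (d = 1.2) on the planted
  component over a modular baseline raises case positive strength and
  lowers case modularity and mean betweenness on the planted subnetwork
  (one-sided ANCOVA p < 0.05 in ≥ 80% of 50 replicates at n = 40). The
  betweenness direction is topology-dependent: uniform strengthening makes
  direct edges dominate shortest paths (lower betweenness) only when the
  baseline does not contain near-unusable edges whose strengthening opens
  new routes.
* **Determinism.** A full pipeline run (10 subjects, 30 regions) is
  byte-identical on rerun under the same master seed (SHA-256 over all JSON
  outputs); per-stage seeds derive from `SeedSequence(master, spawn_key)`.

## Known limitations

* The two-state clustering is forced: on single-regime data k-means splits
  noise into two clusters and the higher-participation noise cluster is
  labeled integrated. Centroids remain faithful to the underlying regime;
  interpret state labels only when the silhouette supports two clusters.
* Parcel-level spin tests are approximate: with half-sphere (anatomically
  truncated) parcel sets any reassignment-based null is under-dispersed.
  The synthetic atlas avoids this by construction; on real parcellations
  the test inherits the usual mild anticonservativeness reported for
  parcel-based spins.
* Sliding-window states are identifiable only when state dwell times are
  comparable to or longer than the window; see the state-recovery notes.
* The numba-compiled Louvain kernel uses numba's internal RNG seeded from
  the package's seed stream; results are deterministic but not reproducible
  against a pure-numpy reimplementation stream.
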