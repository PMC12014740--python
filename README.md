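# braindyn

Dynamic integration–segregation analysis of parcellated resting-state fMRI.

Cognitive neuroscience increasingly describes the resting brain as switching
between **integrated** states — interregional connections dispersed across
modules, supporting global communication — and **segregated** states —
connectivity concentrated inside functional modules. `braindyn` implements a
complete, tested pipeline for characterizing these dynamics in a case–control
cohort (for example patients with a substance use disorder versus healthy
controls) from parcellated BOLD time series:

1. **Dynamic functional connectivity** — zero-phase band-pass filtering
   (0.01–0.08 Hz) and sliding-window Pearson correlation (22-TR windows,
   1-TR steps), giving one signed connectivity matrix per window.
2. **Cartographic profiling** — per-window community detection by consensus
   Louvain on the asymmetric signed modularity

   ```
   Q = (1/v+) Σij (w+ij − γ e+ij) δ(Mi,Mj) − (1/(v+ + v−)) Σij (w−ij − γ e−ij) δ(Mi,Mj)
   ```

   followed by each region's participation coefficient
   `B_i = 1 − Σ_s (K_is/K_i)²` and within-module degree z-score
   `W_i = (K_is − mean)/sd`; the joint (B, W) histogram is the window's
   cartographic profile.
3. **State extraction** — per-subject k-means (k = 2, correlation distance,
   300 restarts) over the profiles; the cluster with higher mean
   participation is the integrated state. Per-state Fisher-z centroid
   matrices, silhouette scan over k = 2..7, and five dynamic measures
   (fraction time, dwell time, total transitions, sample entropy,
   Lempel–Ziv complexity).
4. **Network-based statistic (NBS)** — edgewise ANCOVA (group effect
   adjusted for age, sex, education, mean framewise displacement) on
   Fisher-z centroid edges, connected components over suprathreshold edges,
   and Freedman–Lane permutation control of the family-wise error on
   component size.
5. **Graph metrics** — positive/negative strength, global/local efficiency,
   functional complexity at thresholds, Onnela clustering, characteristic
   path length, null-normalized small-world metrics, mean betweenness
   centrality and signed modularity, on whole state centroids and on
   NBS-identified subnetworks, with group ANCOVA + Benjamini–Hochberg FDR.
6. **Spatial and clinical associations** — Spearman correlations between
   regional significant-edge counts and receptor-like density maps, tested
   with spatial-autocorrelation-preserving *spin* permutations (cortex) and
   within-hemisphere shuffling (subcortex); Pearson partial correlations
   between case-group network metrics and consumption history.

A first-class synthetic cohort generator (`braindyn.synthetic`) produces
multi-subject data with the exact structure the pipeline assumes — a
two-state Markov chain alternating between a block-modular (segregated) and
a uniform (integrated) covariance regime, planted case–control connectivity
effects, subject covariates, and spatially autocorrelated cortical maps — so
every stage is testable end-to-end without access to imaging data.

## Worked example

```python
import numpy as np
from braindyn import synthetic, dfc, cartography, states

regimes = synthetic.default_regimes()            # 100 regions, 5 modules
spec = synthetic.CohortSpec(n_per_group=(1, 0), n_timepoints=300, seed=11)
subject = synthetic.generate_cohort(spec, regimes).subjects[0]

windows = dfc.sliding_window_dfc(subject.series, window_length=22, step=1)
profiles = cartography.window_cartography(
    windows, repetitions=10, seed=5, b_bins=10, z_bins=10
)
result = states.subject_states(windows, profiles, restarts=100, seed=7)

est = result.state_labels == "integrated"
print("windows:", windows.n_windows)
print("fraction integrated:", round(est.mean(), 3))
print("mean participation:", {k: round(v, 3) for k, v in result.mean_participation.items()})
print("transitions:", result.dynamics["total_transitions"])
```

Output:

```
windows: 279
fraction integrated: 0.312
mean participation: {'integrated': 0.69, 'segregated': 0.562}
transitions: 54
```

This subject spends 31% of windows in the integrated state; integrated
windows carry a clearly higher mean participation coefficient (0.69 versus
0.56), i.e. their connections are dispersed across modules rather than
concentrated inside them, and the subject switches state 54 times over the
279 windows.

The same analysis runs from the shell:

```bash
braindyn simulate --out data/ --n-per-group 10 10 --seed 1
braindyn run --config config.yaml --data data/ --out results/
```

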