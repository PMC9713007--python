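# ridgeconn

Ridge-regularized partial-correlation connectomics: from ROI time series to
group inference and machine-learning classification, with a synthetic
cohort generator that gives every stage known ground truth.

The package is aimed at researchers analyzing resting-state functional
connectivity between brain regions (or any multivariate time-series
network) who want the full published workflow — partial-correlation
connectomes, graph topology over a sparsity range, permutation-based group
statistics, and an SVM classifier — as tested, reproducible library code.

## The analysis

1. **Connectivity.** For each subject's timepoints × ROI matrix, columns
   are standardized and the Tikhonov-regularized precision
   `Θ = (Σ̂ + αI)⁻¹` yields partial correlations
   `ρᵢⱼ = −Θᵢⱼ/√(Θᵢᵢ Θⱼⱼ)`, Fisher-transformed to `z = atanh(ρ)`.
   Unlike full Pearson correlation, partial correlation separates direct
   from indirect coupling; the ridge keeps it stable when timepoints are
   scarce.
2. **Topology.** Each z-matrix is thresholded at every sparsity in
   [0.05, 0.40] (step 0.01) into weighted graphs, on which clustering
   (Cp), characteristic path length (Lp), strength (Sp), local/global/nodal
   efficiency, Louvain modularity (Q), betweenness centrality, and the
   small-world indices σ and ω (against degree-preserving random and
   lattice reference nulls) are computed. Curves over the grid are reduced
   to area-under-curve (AUC) features: `7 + 2N` per subject.
3. **Group inference.** The network-based statistic (NBS) finds connected
   components of suprathreshold edge-wise GLM effects, with family-wise
   error control from the Freedman–Lane permutation null of the largest
   component; AUC features are tested by max-statistic permutation GLM;
   clinical scores are related to topology by covariate-controlled partial
   correlation with Bonferroni adjustment.
4. **Classification.** LASSO (repeated-CV penalty choice) selects features
   for a linear SVM (`C = 1`) evaluated by repeated stratified 5-fold CV
   with fold-wise min-max scaling, reported as accuracy / sensitivity /
   specificity / kappa / ROC-AUC with a label-permutation p-value.

## Worked example

Simulate a two-group cohort (20 patients vs 20 controls, 60 ROIs, 196
timepoints) with a planted 8-edge subnetwork of increased partial
correlation (Δρ = +0.3), then detect it:

```python
import numpy as np
from ridgeconn import (
    CohortConfig, PlantedEdge, simulate_cohort,
    connectivity_from_timeseries, Design, nbs_test,
)

planted = [PlantedEdge(*e, 0.3) for e in
           [(0, 1), (0, 2), (1, 3), (2, 4), (3, 5), (4, 6), (5, 7), (6, 8)]]
cohort = simulate_cohort(CohortConfig(
    n_per_group=20, n_nodes=60, n_timepoints=196,
    planted_edges=tuple(planted), seed=1,
))
stack = [connectivity_from_timeseries(s, alpha=0.1) for s in cohort.subjects]
group = (cohort.phenotypes["group"] == "patient").to_numpy(int)
res = nbs_test(stack, Design.two_group(group),
               p_primary=0.001, n_perm=1000, direction="positive", seed=2)
top = res.components[0]
print(f"component: {top.n_edges} edges / {top.n_nodes} nodes, "
      f"p_perm = {top.p_perm:.4f}")
```

```
component: 10 edges / 11 nodes, p_perm = 0.0010
```

The significant component contains all 8 planted edges (plus two noise
edges that happened to attach to it) at the smallest p-value 1000
permutations can resolve (+1-corrected, 1/1001 ≈ 0.001). On a null cohort
(no planted edges) the same call returns only small components with
p ≫ 0.05.

The full pipeline — simulation, connectomes, metric curves, AUC features,
NBS, max-statistic GLM, clinical correlations, classification — runs from
one config:

```bash
ridgeconn run --config run.yaml --out results_dir --seed 1
```

or stage by stage (`ridgeconn simulate / connectome / metrics / nbs /
stats / classify`). All artifacts are plain TSV/CSV/JSON with a manifest;
identical config + seed reproduces byte-identical files.

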