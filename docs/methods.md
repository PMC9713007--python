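# Methods

`ridgeconn` implements a resting-state functional-connectome analysis that
runs from ROI time series to group inference and individual-level
classification. This note records the models, the defaults and why they
were chosen, the numerical conventions, and what the synthetic validation
does and does not demonstrate.

## Connectivity model

Each subject contributes a timepoints × nodes matrix of ROI time series.
Columns are z-scored, so the sample second-moment matrix is a correlation
matrix `Σ̂`. Connectivity is the partial correlation implied by the
Tikhonov-regularized precision

    Θ = (Σ̂ + αI)⁻¹,    ρᵢⱼ = −Θᵢⱼ / √(Θᵢᵢ Θⱼⱼ),

followed by Fisher's r-to-z transform `z = atanh(ρ)`. Partial correlation
removes the linear influence of all other nodes, distinguishing direct from
indirect coupling; the ridge `αI` keeps the inverse well conditioned when
timepoints do not greatly exceed nodes (196 timepoints for 60–246 nodes in
the intended regime).

* `α` defaults to **0.1** after unit-variance standardization. On the
  correlation scale this is a mild shrinkage — large enough to handle
  rank-deficient data, small enough that at `α = 0` the estimator is
  verified against an independent regression-residual oracle to 1e−8.
  There is no canonical published value for this parameter in the
  connectomics tools this mirrors, so it is exposed everywhere.
* `α = 0` on singular data raises with an instruction to use a positive
  ridge rather than silently pseudo-inverting.
* Fisher-z inputs within 1e−9 of ±1 are clipped to 1 − 1e−12 (round-off);
  larger violations are contract errors and raise.

## Thresholding onto the sparsity grid

A sparsity `s` keeps the `floor(s·N(N−1)/2)` upper-triangle entries with the
largest **signed** z-values as weighted, undirected edges; ties break by
lexicographic (i, j). Signed ranking (not |z|) retains the strongest
positive couplings, which is required because every weighted metric below
assumes positive weights; if a grid point would retain a non-positive
weight, the call fails loudly, flagging a grid too dense for the data.
`floor` is used for the edge count so the nominal sparsity is never
exceeded. The default grid is [0.05, 0.40] in steps of 0.01 (36 points).

## Graph metrics

All metrics operate on the positively weighted graph at one grid point.
Weights are first normalized by the graph maximum, and shortest paths use
edge length `1/weight` (strong connections are short). Conventions:

* **Cp** — Onnela geometric-mean weighted clustering, averaged over all
  nodes (degree < 2 contributes 0). The attribute name does not pin a
  variant; Onnela's is the common choice for normalized weights, and with
  unit weights it reduces exactly to binary clustering (verified against a
  Floyd–Warshall brute-force oracle on small graphs).
* **Lp** — mean of *finite* pairwise distances; **E_glob**, **E_nodal** —
  mean inverse distance with unreachable pairs scoring 0. These choices
  keep every grid point computable when sparse graphs disconnect.
* **E_loc** — mean over nodes of the global efficiency of each node's
  neighbor-induced subgraph.
* **Sp** — mean nodal strength of the raw (unnormalized) weights.
* **Q** — modularity of the best of `louvain_restarts` (default 10) seeded
  Louvain runs; Louvain is order-dependent and restarts stabilize the
  reported optimum.
* **btwn.cent** — weighted betweenness on `1/weight` lengths, unnormalized
  (a star center with k leaves scores k(k−1)/2).
* **σ** = (Cp/⟨Cp_rand⟩)/(Lp/⟨Lp_rand⟩), **ω** = ⟨Lp_rand⟩/Lp − Cp/⟨Cp_latt⟩,
  averaged over `n_refs` (default 20) reference graphs. Random references
  are Maslov–Sneppen double-edge swaps (`n_swaps_per_edge · |E|` attempts)
  with the weight multiset randomly reassigned; lattice references accept
  only swaps that strictly reduce the total ring distance of the edge set,
  with weights traveling alongside. Reference sampling error is absorbed
  into test tolerances. If every reference is triangle-free (tiny, very
  sparse graphs), σ/ω are undefined and downstream feature assembly raises
  with an explanation rather than propagating NaN.

Each metric traced over the grid is reduced to its trapezoidal area under
the curve (AUC), removing single-threshold dependence. The feature table
holds one column per global attribute and per nodal attribute × ROI. By
default `E_loc` is excluded from the feature table, giving `7 + 2N` columns
(499 for a 246-ROI atlas); `include_e_loc=True` adds it back. Both
behaviors exist because the attribute is computed in the topology stage yet
a 7-global feature space is what the classification stage consumes.

## Network-based statistic

The NBS operates on the *unthresholded* Fisher-z matrices. For each edge an
OLS GLM (intercept + group + optional nuisance covariates) yields a
t-statistic; edges with `t > t_crit` — the one-sided upper quantile at the
primary p (default 0.001) with the GLM's residual df — form a graph whose
connected components are the candidate effects. One direction is tested per
run; the opposite direction negates the contrast.

The family-wise null is built by Freedman–Lane permutation: the
nuisance-only reduced model is fitted once, its residual rows are permuted,
pseudo-responses are reconstructed, and the full model is refitted. Each
permutation records the largest component as the pair (edge count,
mass), where mass is the summed t-excess over the threshold, and the pair
is compared lexicographically with each observed component. Edge count
remains the primary extent measure; the mass tie-break exists because a
purely integer-valued null is so discrete at stringent primary thresholds
that the test rejects far below its nominal level — with the tie-break the
measured family-wise error on null cohorts sits at the nominal 5% (checked
at 0.07 with a [0.02, 0.09] tolerance band).

Permutation p-values use the +1 correction `(1 + #extreme)/(n_perm + 1)` by
default, which can never return 0; `paper_convention=True` switches to the
raw `#extreme/n_perm` count some publications report.

## Group inference on AUC features

The same GLM/Freedman–Lane machinery tests each AUC feature two-sided
(|t|), with FWE control by the permutation distribution of the maximum |t|
within each feature *family*. The default family structure puts every
global attribute in its own singleton family and groups each nodal
attribute across all ROIs — so a nodal attribute's correction spans the
atlas while each global attribute is tested alone. The family partition is
configurable because other partitions are defensible.

Clinical association is Pearson partial correlation: both variables are
residualized on [intercept | covariates] (default controls: age, education,
nicotine-dependence score), with p from the t distribution on `n − k − 2`
df and Bonferroni correction across the full attribute × clinical-variable
grid.

## Classification

L1-penalized logistic regression over a 30-point geometric penalty path
(glmnet-style `λ_max` down to `λ_max/100`) selects features; the penalty is
chosen by deviance averaged over `lasso_repeats × lasso_folds` stratified
CV (default 10 × 5), `lambda_rule='min'` by default (retains more features;
`'one_se'` gives the sparsest model within one SE). The classifier is a
linear SVM at fixed `C = 1` under repeated stratified 5-fold CV (default
100 repeats). Per training fold, features are min-max scaled to [0, 1] and
the learned parameters applied to the test fold (test values may fall
outside [0, 1]; constant training columns map to 0).

Two selection modes:

* `nested` (default) — LASSO re-run inside every training fold; no test
  information reaches selection or scaling (asserted by instrumenting the
  selection calls).
* `paper` — selection once on the full data before CV, the common published
  shortcut. It leaks test folds into selection and empirically does not
  underperform nested selection; it exists to replicate that procedure.

Performance is reported as accuracy, sensitivity (patient class),
specificity, and Cohen's kappa in percent, mean ± sd over all
repeats × folds, plus the ROC area of pooled per-repeat decision values
(Mann–Whitney concordance, ties 0.5). Significance is a one-tailed
label-permutation test on mean CV accuracy (+1-corrected by default).

## Synthetic cohort generator

The generator provides ground truth for every stage. A sparse backbone
precision matrix (Erdős–Rényi support at `base_density`, constant
off-diagonal magnitude 0.2 with random signs, diagonal loaded to strict
dominance) is shared by both groups; each planted edge shifts the
*partial-correlation* scale of group 2 by a signed delta. Planting solves
the precision entry exactly from the target, and any positive-definiteness
repair loads both groups' diagonals equally and re-solves, so group
differences off the planted set are exactly zero and the planted deltas are
exact by construction.

Subjects are stationary zero-mean Gaussian series: correlated innovations
from the group covariance pass through a per-node AR(1) filter
`x_t = φx_{t−1} + √(1−φ²)e_t` with a stationary start, which injects
temporal smoothness (default φ = 0.3, a mild value typical of filtered BOLD
series) while leaving the contemporaneous covariance exactly equal to the
target. Covariates (age ≈ N(34.4, 8.8²) years, education ≈ N(13.3, 3.9²)
years, nicotine-dependence score ≈ N(6.0, 2.7²)) are drawn identically for
both groups, emulating a matched design. Clinical scores are linear in a
cohort-standardized network summary (mean ridge partial correlation over
the planted edges) plus Gaussian noise, with intercepts and spreads sized
like anxiety/psychiatric rating scales; a zero coefficient yields scores
independent of the connectome.

The desk-scale validation cohort is 20 vs 20 subjects, 60 nodes, 196
timepoints — structurally faithful to a two-group resting-state study while
small enough that the calibration suites (hundreds of simulated cohorts)
run in minutes. The generator does **not** emulate hemodynamics, scanner
noise, head motion, atlas geometry, or spatial autocorrelation between
ROIs; passing tests demonstrate statistical correctness of the estimators
and inference machinery under the stated Gaussian model, not performance on
real fMRI data, and the planted effect sizes are calibration choices rather
than estimates of any real study's effects.

## Reproducibility

Every random draw descends from a single run seed through named
`numpy.random.SeedSequence` substreams (one per pipeline stage, spawned per
subject/permutation consumer), so identical configuration reproduces
byte-identical artifacts and changing one stage's stream leaves the others
untouched. All artifacts are plain text (TSV/CSV/JSON); the run manifest
records parameters, versions, and an input hash. The acceptance script
(`scripts/acceptance.py`) re-runs the full analysis at the desk scale:
NBS and max-statistic permutation counts of 1000–2000 and 5 reference
networks per graph keep the end-to-end run in a few minutes while leaving
every reported quantity Monte-Carlo-stable at the precision reported.

## Known limitations

* σ/ω are undefined on graphs whose references are all triangle-free;
  the feature assembler raises rather than imputing.
* The NBS mass tie-break makes the max statistic effectively continuous
  but departs from toolboxes that rank by raw edge count; with large
  observed components the two orderings agree.
* Latticization uses ring distance on the node index order, which is
  arbitrary for brain graphs; it matches the standard latticization null
  and only enters ω through the reference clustering average.
* `paper` selection mode intentionally reproduces a leaky published
  procedure; its accuracy estimates are optimistic and `nested` should be
  preferred for new analyses.
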