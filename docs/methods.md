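# Methods

## Hyper-network construction

Each ROI's z-scored mean time series `x_m ∈ R^d` is modelled as a sparse
linear combination of the other ROIs' series, `x_m = A_m α_m + τ_m`,
where the design `A_m` is the full series matrix with column `m` zeroed
so an ROI never predicts itself.  The weights solve

    min_α  ‖x_m − A_m α‖₂² + λ_eff ‖α‖₁ ,

taken exactly in this form (no ½ factor, no 1/d normalization).  The
objective convention is immaterial to the recovered edge structure
because the penalty is standardized: `λ_eff = λ_rel · λ_max` with
`λ_max = 2·max_j |a_jᵀ x_m|`, the smallest penalty whose optimum is the
all-zero vector.  λ_max is computed **per regression**, not globally,
which guarantees that `λ_rel = 1` yields an empty support for every ROI
of every subject and makes `λ_rel` comparable across subjects and
datasets.  The default grid is `λ_rel ∈ {0.1, …, 0.9}` (step 0.1).

The solver is cyclic coordinate descent on the Gram form of the
objective (`numba`-compiled; coordinate update = soft threshold at
λ_eff/2 divided by the column's squared norm), tolerance 1e-6 on the
maximum coefficient change, at most 10 000 sweeps, warm-started along
the λ grid from sparser to denser solutions.  Non-convergence raises a
warning and returns the best iterate.  Weights with magnitude above
1e-8 count as support — numerical solvers leave dust below that.

One hyper-edge per (ROI, λ) pair is emitted as `{m} ∪ support(α_m)`.
Two normalizations keep the hypergraph well-defined:

* singleton edges (empty support) are dropped — they contribute nothing
  to any clustering coefficient or pattern;
* duplicate node sets within a subject are merged, keeping the smallest
  λ_rel as provenance; duplicates would otherwise inflate node degrees
  by an arbitrary multiplicity.

Because merged edges carry their smallest λ, restricting a built
network to edges with `λ_rel ≤ c` is exactly the network rebuilt on the
grid prefix up to `c`; λ-grid sweeps exploit this instead of re-solving.

## Hypergraph clustering coefficients

For node `v` with neighbor set `N(v)` and incident-edge star `S(v)`:

* `HCC1(v) = 2 Σ_{u<t ∈ N(v)} 1[∃e: u,t ∈ e, v ∉ e] / (|N(v)|(|N(v)|−1))`
* `HCC2(v) = 2 Σ_{u<t ∈ N(v)} 1[∃e: u,t,v ∈ e] / (|N(v)|(|N(v)|−1))`
* `HCC3(v) = 2 (Σ_{e∈S(v)} (|e|−1) − |N(v)|) / (|N(v)|(|S(v)|−1))`

The indicators are existence indicators over unordered pairs; the
factor 2 against the ordered-pair denominator puts HCC1 and HCC2 in
[0, 1].  For HCC3 the grouping above is the only one that is zero for a
disjoint star and nonnegative in general (`Σ(|e|−1)` counts neighbors
with multiplicity, so it is at least `|N(v)|`).  Degenerate inputs
(`|N(v)| < 2`, or `|S(v)| ≤ 1` for HCC3) return 0: no clustering
evidence.  Features are computed on the pooled all-λ hyper-network —
one incidence matrix per subject — rather than per-λ curves.

Confound handling replaces each feature column by its least-squares
residual against `[1, age, sex, education]` plus the column mean (so
scales stay interpretable); it is off by default and exercised in both
null and confounded regimes by the generator's optional label-dependent
covariate shift.  Selection uses the two-sample KS statistic per column
(exact p-values when both groups have ≤ 25 subjects, asymptotic
otherwise) with Benjamini–Hochberg adjustment; a column is selected
when the adjusted p falls below q = 0.05.

## Subgraph patterns and FSFS selection

Hyper-edge node sets are the subgraph patterns; within each group the
union over subjects is deduplicated.  A pattern's group frequency is
the fraction of subjects whose network contains an edge with **exactly**
that node set (a `superset` containment mode is available as a config
alternative), counted once per subject so frequencies are proper
fractions.  The discriminative score is the absolute frequency
difference; the selection objective is the sum of selected scores under
per-group cardinality caps, for which per-group top-t ranking is the
exact maximizer.  The default threshold is K = 0.25 (sweepable
0.20–0.30 in steps of 0.01), and balancing truncates both groups to
t = min of the two post-threshold counts.  Ties in score break
deterministically: smaller pattern first, then lexicographic node
order.

## Kernels

* **Region view**: RBF kernel `exp(−γ‖x_i−x_j‖²)` on the selected
  feature columns; γ defaults to `1/(p · median column variance)`
  (fallback `1/p` when the median variance is 0).
* **Subgraph view**: each subject becomes a labeled graph on the fixed
  ROI node set — the clique expansion of the subject's hyper-edges that
  match a selected pattern, with ROI identity as the initial node
  label — compared by the Weisfeiler–Lehman subtree kernel with h = 3
  refinement rounds (configurable).  Label compression uses one global
  exact dictionary (no hash buckets, hence no collisions), and the
  kernel sums label-histogram dot products over rounds 0…h before
  normalization.  Keeping all ROIs as nodes with identity labels makes
  node correspondence across subjects meaningful; an edgeless graph
  still has positive self-similarity, so normalization is always
  defined.

Both kernels are cosine-normalized (`K*(i,j) = K(i,j)/√(K(i,i)K(j,j))`)
**before** combination, and fused as `α·K_region + (1−α)·K_subgraph`,
a convex combination of PSD matrices.

The conversion from selected patterns to per-subject graphs is a design
choice (clique expansion of matched patterns, default) with the
whole-network expansion available via `subject_graph(net, None)`.

## Cross-validation and classification

Repeated stratified k-fold CV (defaults: 10 folds × 100 repeats; the
heavier built-in experiments use 3–10 repeats).  With the default
`selection_scope='fold'`, KS/FDR selection, FSFS selection, and the
RBF bandwidth are fit on the training subjects of each outer fold only;
`'global'` scope fits them once on everyone and is provided for
comparison but is optimistically biased.  The kernel weight α (grid
0…1 step 0.1 by default) and SVM cost (grid 2⁻⁵…2⁵ by default) are
chosen per outer fold by an inner stratified CV on the training
subjects; the inner loop reuses the outer fold's feature selection
rather than re-nesting it — a standard compromise that does not touch
test data.  If a fold selects no region features, only α = 0 is
realizable (and symmetrically for patterns); a fold with neither view
predicts the training majority class.  Patients (label 1) are the
positive class.  Per repeat, accuracy/sensitivity/specificity come from
the confusion matrix pooled over folds and AUC from the pooled decision
values (midrank Mann–Whitney); reported metrics are arithmetic means
over repeats.

Feature-importance utilities follow the classic definitions: Relief
with every instance as anchor, min-max column scaling, and Euclidean
nearest hit/miss; permutation p-values are `(1 + #{perm ≥ obs})/(B+1)`.

## Synthetic cohorts

The generator draws each subject's series from a multivariate normal
with AR(1) temporal filtering (`y_t = ρ y_{t−1} + √(1−ρ²) ε_t`,
ρ = 0.3 by default) and z-scores every ROI.  The baseline covariance
inverts a block-diagonal precision matrix (blocks of 5 ROIs, positive
partial correlations), giving every ROI genuine sparse predictors — 
structure the regression stage can recover.  Group 1 additionally
receives a rank-one common component `v vᵀ` with loading
`v_i = √(δ/2)` on a seeded random subset of "perturbed" ROIs: a shared
latent signal that raises their pairwise correlations, stays positive
definite by construction (ridge jitter guards the Cholesky anyway), and
vanishes exactly at effect size δ = 0, making the two groups
label-exchangeable in the null case.  At the standard study conditions
used throughout the built-in experiments — 30+30 subjects, 20 ROIs,
120 timepoints, 4 perturbed ROIs, δ = 2.0 — the perturbed pairs gain
roughly +0.4 correlation, a strong but not degenerate effect.
Covariates (age ~ N(70, 5²), sex ~ Bernoulli(0.5), education ~
N(12, 3²)) are independent of the label unless a shift is configured.
Defaults for atlas-scale work are 90 ROIs × 238 timepoints.

What the generator does **not** emulate: voxel-level structure,
hemodynamic response, scanner noise spectra, motion artifacts, site
effects, or realistic between-subject heterogeneity of the connectome.
Passing tests therefore certify the pipeline's statistical machinery —
leakage-free selection, calibrated nulls, signal recovery under the
stated covariance model — not clinical performance on real cohorts.

## Numerical and reproducibility choices

* Support threshold 1e-8; solver tolerance 1e-6; KS exact/asymptotic
  switch at group size 25; kernel PSD checks at eigenvalue −1e-8;
  normalization unit-diagonal tolerance 1e-10.
* All randomness flows from one master seed through named substreams
  (simulation, fold shuffling, permutations); reruns are byte-identical.
* Every artifact written by the pipeline carries a 16-hex config hash;
  consuming an artifact under a different hash raises.
* Deterministic tie-breaks everywhere a ranking is truncated (patterns)
  or a grid is searched (first best (α, C) combination wins).

## Limitations

* Group-lasso / elastic-net edge construction, weighted hyper-edges,
  and windowed (dynamic) hyper-networks are out of scope.
* Pattern matching is whole-edge equality; general frequent-subgraph
  mining is not attempted.
* The inner model-selection loop shares the outer fold's feature
  selection (see above); fully re-nested selection would multiply cost
  by the inner fold count.
* Relief and the permutation test are reporting utilities; they do not
  feed back into the classifier.
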