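# hyperbrain

Hyper-network modelling and multi-kernel classification of two cohorts
from ROI-level resting-state fMRI time series.

Conventional functional-connectivity analysis reduces brain interactions
to pairwise correlations.  `hyperbrain` instead builds, for every
subject, a **hyper-network**: each region of interest (ROI) `m` seeds a
hyper-edge containing `m` together with the ROIs whose time series
jointly predict it under an l1-regularized regression

    min_α  ‖x_m − A_m α‖² + λ‖α‖₁ ,

where `x_m` is ROI m's z-scored mean series and `A_m` stacks all other
ROIs' series (column m zeroed).  The penalty is expressed on a relative
scale λ ∈ (0, 1] against the per-regression λ_max at which the solution
becomes all-zero, and the construction is repeated over the grid
λ ∈ {0.1, …, 0.9} so hyper-edges capture interactions at multiple
sparsity levels.

From each subject's hypergraph `G = (V, E)` with incidence matrix `H`
(node degrees `d(v) = Σ_e H(v,e)`, co-membership adjacency
`A = HHᵀ − D_v`) the package extracts two complementary feature
families:

* **Region features** — three hypergraph clustering coefficients per
  ROI (HCC₁: neighbor pairs connected without the node; HCC₂: connected
  through the node; HCC₃: overlap among the node's hyper-edges),
  optionally residualized against age/sex/education, and screened by a
  two-sample Kolmogorov–Smirnov test with Benjamini–Hochberg FDR
  control (q = 0.05).
* **Subgraph features** — hyper-edge node-set patterns scored by their
  between-group frequency difference `S(g) = |fq(g|D₊) − fq(g|D₋)|`,
  thresholded at `K = 0.25` and balanced to equal per-group counts
  (FSFS selection).

Subjects are then compared through two kernels — an RBF kernel on the
selected region features and a Weisfeiler–Lehman subtree kernel on the
clique expansion of each subject's selected patterns — which are cosine
normalized and fused as `K(α) = α·K_region + (1−α)·K_subgraph`,
`α ∈ [0, 1]`, inside a soft-margin SVM.  Evaluation is repeated
stratified 10-fold cross-validation with feature selection nested
inside the training folds; α and the SVM cost are chosen by an inner
grid search.

A synthetic-cohort generator with a planted covariance difference
(a latent component shared by a chosen subset of "perturbed" ROIs in
group 1) makes the whole pipeline testable without clinical data.

## Worked example

```python
from hyperbrain import SimulationConfig, simulate_cohort, CVConfig, cross_validate
from hyperbrain.pipeline import build_cohort_networks

config = SimulationConfig(n_group0=30, n_group1=30, n_rois=20,
                          n_timepoints=120, n_perturbed_rois=4,
                          effect_size=2.0, seed=42)
cohort = simulate_cohort(config)
networks = build_cohort_networks(cohort)
print("perturbed ROIs:", sorted(cohort.ground_truth_perturbed))
print("mean hyper-edges per subject:",
      round(sum(len(n.edges) for n in networks) / len(networks), 1))

cv = CVConfig(n_folds=10, n_repeats=5, seed=7,
              alpha_grid=(0.0, 0.3, 0.5, 0.7, 1.0),
              svm_cost_grid=(0.125, 1.0, 8.0), inner_folds=3)
report = cross_validate(networks, cohort.labels, cv)
print(f"accuracy    {report.accuracy:.3f}")
print(f"sensitivity {report.sensitivity:.3f}")
print(f"specificity {report.specificity:.3f}")
print(f"AUC         {report.auc:.3f}")
```

prints

```
perturbed ROIs: [1, 8, 12, 13]
mean hyper-edges per subject: 128.1
accuracy    0.977
sensitivity 0.953
specificity 1.000
AUC         0.998
```

Four of the twenty ROIs carry a planted group difference; each subject
yields ≈128 deduplicated hyper-edges across the λ grid, and the fused
multi-kernel SVM recovers the group difference almost perfectly, with
sensitivity (patient detection rate) and specificity (control detection
rate) reported separately.  On cohorts generated with `effect_size=0`
the same pipeline stays at chance accuracy — the nested, fold-scoped
feature selection does not leak labels.

## Command line

```sh
hyperbrain simulate --n-group0 30 --n-group1 30 --n-rois 20 \
    --n-timepoints 120 --effect-size 2.0 --seed 1 --out cohort/
hyperbrain build-hypernet --manifest cohort/manifest.csv \
    --lambda-grid 0.1:0.9:0.1 --out nets/
hyperbrain features --networks nets/ --manifest cohort/manifest.csv --out feats/
hyperbrain select-subgraphs --networks nets/ --manifest cohort/manifest.csv \
    -K 0.25 --out subs/
hyperbrain classify --manifest cohort/manifest.csv --networks nets/ \
    --folds 10 --repeats 10 --seed 7
hyperbrain run-all --config config.yaml --out results/
hyperbrain sweep --config config.yaml --parameter K --values 0.20:0.30:0.01
```

## Layout

| module | contents |
| --- | --- |
| `hyperbrain.synthetic` | cohort generator, TSV/manifest round-trip |
| `hyperbrain.hypernet` | λ standardization, coordinate-descent lasso, incidence algebra |
| `hyperbrain.region_features` | HCC₁/HCC₂/HCC₃, confound residualization, KS+FDR selection |
| `hyperbrain.subgraphs` | pattern extraction, discriminative scores, balanced FSFS selection |
| `hyperbrain.kernels` | RBF kernel, WL subtree kernel, normalization, fusion |
| `hyperbrain.classification` | precomputed-kernel SVM, nested CV, ROC/AUC, Relief, permutation test |
| `hyperbrain.pipeline` / `hyperbrain.cli` | end-to-end orchestration, sweeps, `hyperbrain` CLI |

See `docs/methods.md` for the modelling assumptions, parameter
defaults, and numerical choices.
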