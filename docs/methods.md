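# Methods

## Problem and model

`connectoml` implements a multimodal brain-network discrimination analysis
for two-group case–control designs (the motivating application is
distinguishing schizophrenia patients from controls, and first-episode from
chronic patients, using three MRI modalities). The pipeline works entirely
on region-level derivatives — it never touches raw images — and consists of
four stages:

1. **Per-subject network construction.** Three weighted, undirected
   networks over a common ROI parcellation (268 nodes in the reference
   atlas; a parameter here):

   * *Gray-matter network (GMN).* Each ROI contributes a bag of voxel-wise
     gray-matter volume values. Each bag's probability density is estimated
     by Gaussian-kernel KDE with Silverman's rule-of-thumb bandwidth,
     evaluated on a single uniform grid shared by all ROIs of a subject
     (512 points spanning the pooled value range, padded by three pooled
     bandwidths). Edges are a KL-divergence-based similarity
     `KLS(p, q) = exp(−[KL(p‖q) + KL(q‖p)])`, computed by discrete
     summation over grid-cell masses with a density floor of 1e-12, so
     KLS ∈ (0, 1] and equals 1 iff the two densities coincide on the grid.
   * *White-matter network (WMN).* Edge weights are streamline (fiber)
     counts between ROI pairs; edges with counts of 2 or fewer are removed
     (strict FN > 2 cutoff). No sparsity sweep is applied — the count
     cutoff already sparsifies.
   * *Functional network (FBN).* Edges are absolute Pearson correlations
     between ROI BOLD time series. The absolute value is a convention
     (negative correlations would break shortest-path metrics); a `raw`
     signed mode exists for export and inspection only.

2. **Sparsity sweep and nodal metrics.** Dense GMN/FBN matrices are
   thresholded at proportional sparsity levels S = 0.10, 0.11, …, 0.40
   (31 levels; endpoints inclusive and configurable), each retaining the
   `round(S·n(n−1)/2)` largest-weight edges **with their weights** (ties at
   the cutoff broken by ascending (row, column) index, which makes
   thresholding deterministic and edge sets nested across S). On every
   network three nodal metrics are computed with edge length ℓ = 1/w:

   * degree centrality DC(i) = Σ_j w(i,j) (strength),
   * nodal efficiency NE(i) = (1/(n−1)) Σ_{j≠i} 1/d(i,j) with 1/∞ = 0,
   * betweenness centrality BC(i) = Σ σ_st(i)/σ_st over unordered pairs,
     normalized by (n−1)(n−2)/2 (so BC ∈ [0, 1] and is comparable across
     sparsity levels).

   Metrics from the sweep are collapsed to one value per node by the
   trapezoidal area under the metric-vs-S curve (so a constant metric v
   integrates to 0.3 v over the default range). Shortest paths and
   betweenness are delegated to C implementations (scipy's Dijkstra,
   igraph's weighted Brandes with exact geodesic multiplicity); the test
   suite verifies both against an exhaustive path-enumeration oracle and
   against networkx.

3. **Discrimination.** Features are the per-ROI, per-metric values of the
   chosen modality combination (e.g. GMN+FBN: 2 × n_rois × 3 features).
   The protocol: stratified 4:1 train/test split; per-feature min–max
   normalization fit on training data only (test values are *not*
   clipped to [0, 1]; constant training features map to 0 with a warning);
   recursive feature elimination dropping the lowest-importance 10% of
   surviving features per refit round, with the retained-set size chosen
   from {1, 2, 5, 10, 20, 50, 100}% of features by mean 10-fold
   cross-validated accuracy on the training set (ties keep the larger
   set); a final refit on all training rows; evaluation on the untouched
   test set (accuracy, sensitivity/specificity with patients as the
   positive class, ROC over decision scores, trapezoidal AUC). Importances
   for RFE are |coefficient| for linear SVM/LR/LDA and impurity importance
   for RF; KNN exposes none, so its RFE ranks by the univariate ANOVA
   F-score (a documented fallback). Hyperparameters are fixed conventional
   defaults (linear SVM C = 1, RF 500 trees, LR L2 C = 1, KNN k = 5); no
   nested tuning.

   Significance of an observed test AUC comes from rerunning the entire
   configured pipeline under B random permutations of the *training*
   labels, with the add-one estimator p = (1 + #{AUC_b ≥ AUC_obs})/(B + 1).

4. **Attribution.** For the best linear model, |coefficients| rank the
   features (eliminated features carry weight 0; ties break by feature
   index). The top `floor(0.05·n)` features are mapped through an
   ROI→subnetwork atlas table (eight functional subnetworks) and summarized
   as proportions per subnetwork and per modality. The real 268-ROI
   assignment is an input the user supplies; a synthetic block mapping is
   bundled for testing only.

Cohort-description statistics (one-way ANOVA, Scheffé post hoc contrasts
on the shared within-group mean square, pooled-variance two-sample t
recomputable from printed mean ± SD summaries, Pearson χ² without
continuity correction) live in `connectoml.stats`. The pooled (Student)
rather than Welch t is used deliberately: it is the form that reproduces
the reference clinical table's printed t statistics.

## Synthetic cohorts

No real cohort is distributed, so a generator produces two-group cohorts
with known planted effects; its job is statistical structure, not
biological realism. Fixed design constants (chosen once):

* ROI base means ~ N(0.5, 0.05²) (arbitrary gray-matter-volume-like units),
  within-ROI voxel SD σ = 0.1, between-subject SD of the subject-level ROI
  mean τ = 0.05.
* `effect_size_gm` is the **standardized between-subject shift of the mean
  regional value**: affected ROIs in group 1 are shifted by
  `effect_size_gm · sqrt(τ² + σ²/n_voxels)`, so a two-sample t on subject
  means has exactly the textbook noncentral-t power at that d.
* Fibers: a structural scaffold (Bernoulli per ROI pair at
  `connection_density`, shared by all subjects of a cohort) carries
  Poisson(`base_fiber_rate`) counts; group-1 edges between affected ROIs
  have their rate multiplied by `effect_size_fn`.
* Time series: a three-factor structured correlation matrix (loadings
  ~ N(0, 0.4²), rescaled to unit diagonal) drives Cholesky-correlated
  innovations filtered by a common AR(1) with φ = 0.3 (which preserves the
  cross-correlation while adding realistic temporal autocorrelation; 50
  burn-in samples are discarded). Group 1 adds `effect_size_fc` to affected
  ROI pairs, then the matrix is repaired to the nearest positive-definite
  correlation by eigenvalue clipping at 1e-6 and unit-diagonal rescaling.
* Randomness: every subject's stream derives from the master seed and the
  subject index (`SeedSequence(seed, spawn_key=...)`), so regeneration is
  bit-identical and enlarging a cohort never perturbs existing subjects.

What the generator does **not** emulate: spatial voxel structure,
atlas-specific anatomy, scanner/site effects, motion artifacts,
non-Gaussian volume distributions, and the dependence between modalities
within a subject (modalities are conditionally independent given group).
Passing tests therefore demonstrate correct *mechanics and calibration* of
the pipeline, not expected performance on real MRI cohorts.

## Calibration and recovery experiments

Two canonical designs (in `connectoml.experiments`) exercise everything
end to end; their sizes were chosen once as the smallest designs at which
the statistical claims are meaningful:

* **Null calibration** — 50 ROIs, 40 subjects/group, 100 voxels/ROI, 230
  time points, all effect sizes zero, GMN+FBN features on a 256-point KDE
  grid. Across replicate cohorts, each classifier's held-out accuracy
  should fall inside the central 95% binomial band around 0.5 in ≥ 90% of
  replicates, and the B = 200 label-permutation test should reject at
  α = 0.05 at roughly its nominal rate. Feature selection is switched off
  in this design: a pure null has no features worth selecting, the type-I
  behaviour of the permutation estimator does not depend on the selection
  step (each permutation replicate reruns whatever pipeline is
  configured), and the full RFE pipeline is exercised and leakage-audited
  by the other experiments.
* **Signal recovery** — as above but 60 subjects/group with
  `effect_size_gm = 1.5` and `effect_size_fc = 0.2` planted in ROIs 0–19,
  all assigned to the subcortical/cerebellum subnetwork of the test atlas.
  The companion functional shift exists because the feature set spans two
  modalities; a purely structural effect would leave the FBN half of the
  feature block uninformative by construction. The linear-SVM+RFE pipeline
  should exceed held-out AUC 0.75 in ≥ 80% of replicates, and the affected
  subnetwork's top-5% attribution share should beat its 40% ROI share as
  often.

The test suite runs these at 50 and 20 replicates respectively;
`scripts/acceptance.py` reports the same quantities at 30 and 12
replicates.

## Numerical choices and edge cases

* KDE grids must be uniform; cell masses (density × Δx, renormalized) are
  the KL summation units, making the two-cell worked example
  0.5 ln 2 + 0.5 ln(2/3) + 0.25 ln(1/2) + 0.75 ln(3/2) ≈ 0.2747 exact.
* Zero-variance ROI bags and constant time series raise degenerate-input
  errors naming the ROI; they cannot be smoothed meaningfully.
* Disconnected node pairs contribute 0 to NE (1/∞); sparse thresholds
  routinely disconnect nodes and this must not error.
* `apply_sparsity` is idempotent and nested across S by the stable
  tie-break; `round` (not floor) fixes the retained edge count.
* Min–max normalization of a constant training feature maps to 0 rather
  than erroring (logged), because RFE legitimately produces such columns
  on permuted labels.
* The permutation-p add-one estimator keeps p ∈ (0, 1]; permutations that
  produce a single-class training vector are skipped (probability ~0 at
  realistic n).
* Stratified splitting delegates to scikit-learn with `test_size =
  round(n/5)` so a 345-subject cohort splits 276/69.

## Known limitations

* Computational cost is dominated by per-threshold Brandes betweenness;
  the 268-ROI reference scale is practical per subject (~seconds) but
  large replicate studies should reduce ROI count, as the bundled
  experiments do.
* The RFE variant runs one elimination trajectory on the full training set
  and cross-validates the candidate subset sizes; it does not re-run the
  trajectory inside each fold (cheaper, and selection still never sees
  test rows).
* Scheffé's conservativeness relative to an unadjusted pairwise contrast
  holds on the shared ANOVA error term; with per-pair error variances the
  ordering can reverse on unlucky draws (the tests state it correctly).
* The chance band and rejection-rate acceptance bounds are Monte-Carlo
  statements; with 50 replicates the nominal-rate check itself has ~10%
  probability of landing outside the stated open interval under perfect
  calibration.
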