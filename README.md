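# connectoml

Multimodal brain-network construction and machine-learning group
discrimination for case–control neuroimaging studies.

Given region-level MRI derivatives for each subject — per-ROI bags of
voxel-wise gray-matter volume values, a symmetric fiber-count matrix from
tractography, and ROI × time BOLD series — `connectoml` builds three
weighted networks per subject, summarizes their topology, and asks whether
network topology discriminates two groups:

* **GMN** (gray-matter network): edges are a Kullback–Leibler
  divergence-based similarity between per-ROI value densities,
  `KLS(p, q) = exp(−[KL(p‖q) + KL(q‖p)])` ∈ (0, 1], with densities from
  Gaussian KDE (Silverman bandwidth) on a shared grid.
* **WMN** (white-matter network): fiber counts, keeping edges with FN > 2.
* **FBN** (functional network): absolute Pearson correlation of time series.

Dense GMN/FBN matrices are swept over sparsity thresholds S = 0.10…0.40
(step 0.01, 31 weighted networks). At every level three nodal metrics are
computed with edge length 1/w — degree centrality (strength), nodal
efficiency (mean inverse shortest-path length), and normalized betweenness
centrality — and each metric is collapsed across the sweep by area under
the metric-vs-S curve, giving 3 × n_ROIs features per modality per subject.

Discrimination follows a leakage-audited protocol: stratified 4:1
train/test split, min–max normalization fit on training data only,
recursive feature elimination with the retained-set size chosen by 10-fold
CV accuracy, five classifiers (linear SVM, random forest, logistic
regression, LDA, KNN), independent-test ROC/AUC, and label-permutation
significance (p = (1 + #{AUC_b ≥ AUC_obs})/(B + 1)). Linear-model weights
are then ranked by |coefficient|, the top 5% of features mapped through an
ROI→subnetwork atlas (eight functional subnetworks), and their distribution
over subnetworks and modalities reported.

Because matched MRI cohorts are rarely public, a synthetic-cohort generator
(`connectoml.synthetic`) produces two-group cohorts with planted,
recoverable effects in all three modalities; every pipeline stage is tested
against it and against analytic or exhaustive oracles. See
`docs/methods.md` for the model, the generator's design constants, and
numerical conventions.

## Worked example

```python
import numpy as np
from connectoml import (
    CohortConfig, generate_cohort, cohort_feature_matrix, discriminate,
    feature_contributions, top_fraction, subnetwork_distribution,
    synthetic_block_mapping,
)

config = CohortConfig(
    n_rois=50, n_subjects_per_group=60, n_voxels_per_roi=100,
    n_timepoints=230, affected_rois=tuple(range(20)),
    effect_size_gm=1.5, effect_size_fc=0.2, seed=42,
)
cohort = generate_cohort(config)                       # 120 subjects
features = cohort_feature_matrix(cohort, ("GMN", "FBN"))  # 120 x 300
results = discriminate(features, ("SVM",), seed=42)
svm = results["SVM"]
print(f"accuracy={svm.accuracy:.3f} auc={svm.auc:.3f}")

ranked = feature_contributions(svm.feature_weights, features.annotations)
top = top_fraction(ranked, 0.05)                       # 15 of 300 features
share, by_modality = subnetwork_distribution(
    top, synthetic_block_mapping(features.annotations["roi"].unique().tolist())
)
print(share.round(3))
```

Output:

```
accuracy=1.000 auc=1.000
medial frontal            0.267
frontoparietal            0.133
default mode              0.533
subcortical/cerebellum    0.067
motor                     0.000
visual I                  0.000
visual II                 0.000
visual association        0.000
Name: proportion, dtype: float64
```

The planted effect in ROIs 0–19 is recovered perfectly on the held-out
subjects (AUC 1.0 at this effect size), and the top-5% features concentrate
in the subnetworks covering those ROIs: the synthetic block atlas assigns
ROIs 0–18 to its first three subnetworks, which together hold
0.267 + 0.133 + 0.533 = 93% of the top features against a 38% ROI share.

A command-line interface mirrors the stages:

```
connectoml simulate  --config cohort.yaml --out cohort/ --seed 1
connectoml metrics   --in cohort/ --modalities gmn,fbn --out metrics.tsv
connectoml classify  --features metrics.tsv --labels cohort/labels.tsv \
                     --modalities gmn,fbn --classifier all --out results/
connectoml attribute --weights results/weights_svm.tsv \
                     --mapping atlas.tsv --fraction 0.05 --out shares.tsv
connectoml stats     --summaries table1.tsv
```

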