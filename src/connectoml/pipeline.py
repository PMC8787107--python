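"""End-to-end glue: cohort -> per-subject networks -> features -> results."""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .classify import (
    ClassificationResult,
    FeatureMatrix,
    PipelineConfig,
    feature_matrix_from_tables,
    permutation_test,
    run_pipeline,
    split_train_test,
)
from .errors import ContractError
from .metrics import nodal_feature_table
from .networks import ConnectivityMatrix, build_fbn, build_gmn, build_wmn
from .synthetic import SyntheticCohort, SyntheticSubject

__all__ = [
    "subject_networks",
    "cohort_feature_matrix",
    "discriminate",
]

MODALITIES = ("GMN", "WMN", "FBN")


def subject_networks(
    subject: SyntheticSubject,
    modalities: Sequence[str] = ("GMN", "FBN"),
    fn_cutoff: int = 2,
    fbn_edge: str = "abs",
    grid_size: int = 512,
) -> dict[str, ConnectivityMatrix]:
    """Build the requested modality networks for one subject."""
    nets: dict[str, ConnectivityMatrix] = {}
    for modality in modalities:
        if modality == "GMN":
            nets["GMN"] = build_gmn(subject.regional_samples, grid_size=grid_size)
        elif modality == "WMN":
            nets["WMN"] = build_wmn(subject.fibers, fn_cutoff=fn_cutoff)
        elif modality == "FBN":
            nets["FBN"] = build_fbn(subject.timeseries, edge=fbn_edge)
        else:
            raise ContractError(f"unknown modality {modality!r}")
    return nets


def cohort_feature_matrix(
    cohort: SyntheticCohort,
    modalities: Sequence[str] = ("GMN", "FBN"),
    s_min: float = 0.10,
    s_max: float = 0.40,
    step: float = 0.01,
    fn_cutoff: int = 2,
    fbn_edge: str = "abs",
    grid_size: int = 512,
) -> FeatureMatrix:
    """Nodal-metric features (AUC-integrated where swept) for a whole cohort."""
    tables: dict[str, pd.DataFrame] = {}
    labels: dict[str, int] = {}
    for subject in cohort.subjects:
        nets = subject_networks(
            subject, modalities, fn_cutoff=fn_cutoff,
            fbn_edge=fbn_edge, grid_size=grid_size,
        )
        tables[subject.subject_id] = nodal_feature_table(
            nets, s_min=s_min, s_max=s_max, step=step
        )
        labels[subject.subject_id] = subject.group_label
    return feature_matrix_from_tables(tables, labels)


def discriminate(
    features: FeatureMatrix,
    classifiers: Iterable[str] = ("SVM", "RF", "LR", "LDA", "KNN"),
    seed: int = 0,
    use_rfe: bool = True,
    n_permutations: int = 0,
    cv_folds: int = 10,
) -> dict[str, ClassificationResult]:
    """Split once, then run every requested classifier on the same split.

    With ``n_permutations > 0`` each result carries a label-permutation p
    value for its test AUC.
    """
    train, test = split_train_test(features, seed=seed)
    results: dict[str, ClassificationResult] = {}
    for name in classifiers:
        config = PipelineConfig(classifier=name, use_rfe=use_rfe,
                                cv_folds=cv_folds, seed=seed)
        result = run_pipeline(config, train, test)
        if n_permutations > 0:
            result.permutation_p = permutation_test(
                config, train, test, result.auc,
                n_permutations=n_permutations, seed=seed,
            )
        results[name] = result
    return results
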