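"""Delimited-text I/O for cohorts, matrices and result tables.

All on-disk formats are plain TSV with ROI-label headers:

* regional samples — long format ``subject_id, roi, voxel_value``;
* fiber / time-series / network matrices — square or rectangular tables
  with an ROI-label header row (and index column for square matrices);
* ``labels.tsv`` — ``subject_id, group``;
* ``ground_truth.yaml`` — the cohort configuration that generated the data.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ContractError
from .networks import ConnectivityMatrix, RegionalSampleSet, ROITimeSeries
from .synthetic import CohortConfig, SyntheticCohort, SyntheticSubject

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_matrix",
    "read_matrix",
    "read_atlas_mapping",
]


def write_matrix(net: ConnectivityMatrix | np.ndarray, path: Path,
                 roi_labels: list[str] | None = None) -> None:
    if isinstance(net, ConnectivityMatrix):
        frame = pd.DataFrame(net.weights, index=net.roi_labels,
                             columns=net.roi_labels)
    else:
        frame = pd.DataFrame(np.asarray(net), index=roi_labels,
                             columns=roi_labels)
    frame.to_csv(path, sep="\t")


def read_matrix(path: Path, modality: str) -> ConnectivityMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return ConnectivityMatrix(
        roi_labels=[str(c) for c in frame.columns],
        weights=frame.to_numpy(dtype=float),
        modality=modality,
        allow_negative=True,
    )


def _write_timeseries(ts: ROITimeSeries, path: Path) -> None:
    pd.DataFrame(ts.values, index=ts.roi_labels).to_csv(path, sep="\t")


def _read_timeseries(path: Path) -> ROITimeSeries:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return ROITimeSeries(roi_labels=[str(i) for i in frame.index],
                         values=frame.to_numpy(dtype=float))


def _write_regional(samples: RegionalSampleSet, subject_id: str,
                    path: Path) -> None:
    rows = []
    for roi, values in zip(samples.roi_labels, samples.samples):
        rows.append(pd.DataFrame({
            "subject_id": subject_id, "roi": roi, "voxel_value": values,
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def _read_regional(path: Path) -> RegionalSampleSet:
    frame = pd.read_csv(path, sep="\t")
    labels, bags = [], []
    for roi, grp in frame.groupby("roi", sort=True):
        labels.append(str(roi))
        bags.append(grp["voxel_value"].to_numpy(dtype=float))
    return RegionalSampleSet(roi_labels=labels, samples=bags)


def write_cohort(cohort: SyntheticCohort, out_dir: Path) -> None:
    """Write one file per subject per modality plus labels and ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = []
    for subject in cohort.subjects:
        sid = subject.subject_id
        _write_regional(subject.regional_samples, sid,
                        out_dir / f"{sid}_gm_samples.tsv")
        write_matrix(subject.fibers, out_dir / f"{sid}_fibers.tsv")
        _write_timeseries(subject.timeseries, out_dir / f"{sid}_timeseries.tsv")
        labels.append({"subject_id": sid, "group": subject.group_label})
    pd.DataFrame(labels).to_csv(out_dir / "labels.tsv", sep="\t", index=False)
    truth = asdict(cohort.ground_truth)
    truth["affected_rois"] = list(truth["affected_rois"])
    with open(out_dir / "ground_truth.yaml", "w") as fh:
        yaml.safe_dump(truth, fh)


def read_cohort(in_dir: Path) -> SyntheticCohort:
    """Read a cohort written by :func:`write_cohort`."""
    in_dir = Path(in_dir)
    labels_path = in_dir / "labels.tsv"
    if not labels_path.exists():
        raise ContractError(f"no labels.tsv under {in_dir}")
    labels = pd.read_csv(labels_path, sep="\t")
    with open(in_dir / "ground_truth.yaml") as fh:
        truth = yaml.safe_load(fh)
    truth["affected_rois"] = tuple(truth.get("affected_rois", ()))
    config = CohortConfig(**truth)
    subjects = []
    for _, row in labels.iterrows():
        sid = str(row["subject_id"])
        subjects.append(SyntheticSubject(
            subject_id=sid,
            group_label=int(row["group"]),
            regional_samples=_read_regional(in_dir / f"{sid}_gm_samples.tsv"),
            fibers=read_matrix(in_dir / f"{sid}_fibers.tsv", modality="WMN"),
            timeseries=_read_timeseries(in_dir / f"{sid}_timeseries.tsv"),
        ))
    return SyntheticCohort(subjects=subjects, ground_truth=config)


def read_atlas_mapping(path: Path) -> pd.DataFrame:
    """Two-column (roi_label, subnetwork) table with a header row."""
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[1] < 2:
        raise ContractError("atlas mapping needs columns (roi_label, subnetwork)")
    return frame
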