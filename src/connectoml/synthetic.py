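"""Synthetic two-group multimodal cohorts with planted, recoverable effects.

The generator emulates the region-level derivatives the pipeline consumes —
per-ROI bags of voxel-wise gray-matter values, integer fiber-count matrices
on a shared structural scaffold, and autocorrelated BOLD-like time series
with a structured cross-correlation — for two groups of subjects. Group 1
carries planted effects confined to a designated ROI set:

* a standardized shift of the mean regional gray-matter value
  (``effect_size_gm``, in units of the between-subject SD of that mean);
* a multiplicative scaling of fiber counts on edges among affected ROIs
  (``effect_size_fn``);
* an additive shift of the time-series correlation on affected ROI pairs
  (``effect_size_fc``), re-projected to the nearest positive-definite
  correlation matrix.

Randomness is reproducible and extension-stable: each subject's stream is
derived from the master seed and the subject's index, so regenerating with
more subjects never perturbs existing ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError, GenerationError

logger = logging.getLogger(__name__)
from .networks import ConnectivityMatrix, RegionalSampleSet, ROITimeSeries

__all__ = [
    "CohortConfig",
    "SyntheticSubject",
    "SyntheticCohort",
    "generate_cohort",
    "generate_regional_samples",
    "generate_fiber_matrix",
    "generate_timeseries",
    "nearest_positive_definite_correlation",
]

# Fixed distributional constants of the generator (documented in the methods
# note): ROI base means, within-ROI voxel SD, between-subject SD of the
# subject-level ROI mean, latent-factor loadings of the functional
# correlation structure, and the AR(1) temporal autocorrelation.
ROI_MEAN_CENTER = 0.5
ROI_MEAN_SPREAD = 0.05
VOXEL_SD = 0.1
SUBJECT_SD = 0.05
N_LATENT_FACTORS = 3
FACTOR_LOADING_SD = 0.4
AR1_PHI = 0.3
#: eigenvalue floor for the positive-definite correlation repair
PD_EIGEN_FLOOR = 1e-6

# stream tags keeping per-subject / cohort-level substreams independent
_STREAM_COHORT = 0
_STREAM_GM = 1
_STREAM_FN = 2
_STREAM_TS = 3


@dataclass(frozen=True)
class CohortConfig:
    """Ground-truth description of a synthetic cohort."""

    n_rois: int = 268
    n_subjects_per_group: int = 30
    n_voxels_per_roi: int = 150
    n_timepoints: int = 230
    affected_rois: tuple[int, ...] = ()
    effect_size_gm: float = 0.0
    effect_size_fn: float = 1.0
    effect_size_fc: float = 0.0
    base_fiber_rate: float = 20.0
    connection_density: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_rois", "n_subjects_per_group", "n_voxels_per_roi",
                     "n_timepoints"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 2:
                raise ConfigurationError(f"{name} must be an integer >= 2, got {value}")
        object.__setattr__(self, "affected_rois", tuple(sorted(self.affected_rois)))
        for r in self.affected_rois:
            if not (0 <= r < self.n_rois):
                raise ConfigurationError(
                    f"affected_rois entry {r} outside [0, {self.n_rois})"
                )
        if not (0.0 <= self.connection_density <= 1.0):
            raise ConfigurationError(
                f"connection_density must be in [0, 1], got {self.connection_density}"
            )
        for name in ("effect_size_gm", "effect_size_fn", "effect_size_fc"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite")
        if self.effect_size_fn < 0:
            raise ConfigurationError("effect_size_fn must be nonnegative")
        if self.base_fiber_rate <= 0:
            raise ConfigurationError("base_fiber_rate must be positive")

    @property
    def roi_labels(self) -> list[str]:
        return [f"ROI{i:03d}" for i in range(self.n_rois)]


@dataclass
class SyntheticSubject:
    subject_id: str
    group_label: int
    regional_samples: RegionalSampleSet
    fibers: ConnectivityMatrix
    timeseries: ROITimeSeries


@dataclass
class SyntheticCohort:
    subjects: list[SyntheticSubject]
    ground_truth: CohortConfig

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.group_label for s in self.subjects])


def _rng(config: CohortConfig, *key: int) -> np.random.Generator:
    """Stable stream derivation: master seed plus a structured spawn key."""
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=key))


# ---------------------------------------------------------------------------
# cohort-level shared structure
# ---------------------------------------------------------------------------

def _roi_base_means(config: CohortConfig) -> np.ndarray:
    rng = _rng(config, _STREAM_COHORT, 0)
    return ROI_MEAN_CENTER + ROI_MEAN_SPREAD * rng.standard_normal(config.n_rois)


def _structural_scaffold(config: CohortConfig) -> np.ndarray:
    """Boolean ROI-pair mask shared by every subject of the cohort."""
    rng = _rng(config, _STREAM_COHORT, 1)
    n = config.n_rois
    iu = np.triu_indices(n, k=1)
    mask = np.zeros((n, n), dtype=bool)
    mask[iu] = rng.random(len(iu[0])) < config.connection_density
    return mask | mask.T


def _base_correlation(config: CohortConfig) -> np.ndarray:
    """Structured positive-definite correlation from a low-rank factor model."""
    rng = _rng(config, _STREAM_COHORT, 2)
    loadings = FACTOR_LOADING_SD * rng.standard_normal(
        (config.n_rois, N_LATENT_FACTORS)
    )
    cov = loadings @ loadings.T + np.eye(config.n_rois)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def nearest_positive_definite_correlation(
    target: np.ndarray, eigen_floor: float = PD_EIGEN_FLOOR
) -> np.ndarray:
    """Repair a symmetric matrix into a positive-definite correlation matrix.

    Eigenvalues are clipped at ``eigen_floor`` and the result rescaled to a
    unit diagonal.
    """
    sym = (target + target.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    vals = np.clip(vals, eigen_floor, None)
    repaired = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    if np.any(d <= 0) or not np.all(np.isfinite(d)):
        raise GenerationError("correlation target could not be repaired")
    out = repaired / np.outer(d, d)
    return (out + out.T) / 2.0


def _group_correlation(config: CohortConfig, group_label: int) -> np.ndarray:
    corr = _base_correlation(config)
    if group_label == 1 and config.effect_size_fc != 0 and config.affected_rois:
        idx = np.asarray(config.affected_rois)
        shifted = corr.copy()
        block = np.ix_(idx, idx)
        shifted[block] = np.clip(shifted[block] + config.effect_size_fc, -0.99, 0.99)
        np.fill_diagonal(shifted, 1.0)
        corr = nearest_positive_definite_correlation(shifted)
    return corr


# ---------------------------------------------------------------------------
# per-subject modalities
# ---------------------------------------------------------------------------

def generate_regional_samples(
    config: CohortConfig, group_label: int, subject_index: int
) -> RegionalSampleSet:
    """Voxel-level gray-matter values per ROI for one subject.

    The subject's ROI mean is the cohort base mean plus a between-subject
    random intercept; in group 1, affected ROIs are shifted so the group
    difference of the *mean regional value* equals ``effect_size_gm`` SD
    units of that mean's sampling distribution.
    """
    rng = _rng(config, _STREAM_GM, subject_index)
    base = _roi_base_means(config)
    subject_means = base + SUBJECT_SD * rng.standard_normal(config.n_rois)
    if group_label == 1 and config.affected_rois:
        # SD of the observed per-subject mean regional value
        sd_mean = np.sqrt(SUBJECT_SD**2 + VOXEL_SD**2 / config.n_voxels_per_roi)
        subject_means[np.asarray(config.affected_rois)] += (
            config.effect_size_gm * sd_mean
        )
    values = subject_means[:, None] + VOXEL_SD * rng.standard_normal(
        (config.n_rois, config.n_voxels_per_roi)
    )
    return RegionalSampleSet(roi_labels=config.roi_labels, samples=list(values))


def generate_fiber_matrix(
    config: CohortConfig, group_label: int, subject_index: int
) -> ConnectivityMatrix:
    """Integer fiber-count matrix on the cohort's shared structural scaffold.

    Counts are Poisson around ``base_fiber_rate``; in group 1, edges whose
    endpoints are both affected ROIs have their rate scaled by
    ``effect_size_fn``.
    """
    rng = _rng(config, _STREAM_FN, subject_index)
    scaffold = _structural_scaffold(config)
    n = config.n_rois
    rates = np.where(scaffold, config.base_fiber_rate, 0.0)
    if group_label == 1 and config.affected_rois:
        idx = np.asarray(config.affected_rois)
        block = np.ix_(idx, idx)
        rates[block] = rates[block] * config.effect_size_fn
    iu = np.triu_indices(n, k=1)
    counts = np.zeros((n, n))
    counts[iu] = rng.poisson(rates[iu])
    counts = counts + counts.T
    return ConnectivityMatrix(
        roi_labels=config.roi_labels, weights=counts, modality="WMN"
    )


def generate_timeseries(
    config: CohortConfig, group_label: int, subject_index: int
) -> ROITimeSeries:
    """Correlated AR(1) Gaussian ROI time series for one subject.

    Innovations are drawn with the group's target cross-correlation (Cholesky
    factorization) and filtered by a common AR(1) coefficient, which leaves
    the cross-correlation of the stationary series at its target.
    """
    if config.n_timepoints <= config.n_rois:
        logger.warning(
            "n_timepoints (%d) <= n_rois (%d): empirical correlation "
            "matrices will be rank-deficient", config.n_timepoints, config.n_rois
        )
    rng = _rng(config, _STREAM_TS, subject_index)
    corr = _group_correlation(config, group_label)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(
            nearest_positive_definite_correlation(corr)
        )
    t_total = config.n_timepoints + 50  # burn-in for the AR(1) filter
    innovations = chol @ rng.standard_normal((config.n_rois, t_total))
    series = np.empty_like(innovations)
    series[:, 0] = innovations[:, 0]
    scale = np.sqrt(1.0 - AR1_PHI**2)
    for t in range(1, t_total):
        series[:, t] = AR1_PHI * series[:, t - 1] + scale * innovations[:, t]
    return ROITimeSeries(
        roi_labels=config.roi_labels, values=series[:, -config.n_timepoints :]
    )


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full two-group cohort (group 0 then group 1)."""
    subjects = []
    n_per_group = config.n_subjects_per_group
    for subject_index in range(2 * n_per_group):
        group = 0 if subject_index < n_per_group else 1
        subjects.append(
            SyntheticSubject(
                subject_id=f"sub-{subject_index:04d}",
                group_label=group,
                regional_samples=generate_regional_samples(
                    config, group, subject_index
                ),
                fibers=generate_fiber_matrix(config, group, subject_index),
                timeseries=generate_timeseries(config, group, subject_index),
            )
        )
    return SyntheticCohort(subjects=subjects, ground_truth=config)


def with_seed(config: CohortConfig, seed: int) -> CohortConfig:
    """Convenience: the same cohort design under a different seed."""
    return replace(config, seed=int(seed))
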