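"""Per-subject brain-network construction.

Three networks are built per subject, one per MRI modality:

* **GMN** (gray-matter network): each ROI's voxel-wise gray-matter volume
  values define a probability density (Gaussian KDE, Silverman bandwidth);
  edges are a Kullback-Leibler divergence-based similarity,
  ``KLS = exp(-(KL(p||q) + KL(q||p)))``, bounded in (0, 1].
* **WMN** (white-matter network): streamline counts between ROI pairs,
  retained when the fiber number exceeds a cutoff (default FN > 2).
* **FBN** (functional network): absolute Pearson correlation between ROI
  BOLD time series.

Dense GMN/FBN matrices are swept over proportional sparsity thresholds
(default S = 0.10 ... 0.40, step 0.01, 31 levels); the retained networks
stay weighted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import gaussian_kde

from .errors import ContractError, DegenerateInputError


#: density floor applied before renormalization, so log-ratios stay finite
DENSITY_FLOOR = 1e-12
#: number of abscissae in the shared per-subject KDE grid
DEFAULT_GRID_SIZE = 512
#: grid padding beyond the pooled value range, in pooled-bandwidth units
GRID_PAD_BANDWIDTHS = 3.0

__all__ = [
    "RegionalSampleSet",
    "DensityVector",
    "ROITimeSeries",
    "ConnectivityMatrix",
    "ThresholdedNetworkSeries",
    "estimate_pdf",
    "symmetric_kl",
    "kls",
    "build_gmn",
    "build_fbn",
    "build_wmn",
    "apply_sparsity",
    "threshold_sweep",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RegionalSampleSet:
    """Per-ROI bags of voxel-level gray-matter volume values for one subject."""

    roi_labels: list[str]
    samples: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.roi_labels) != len(self.samples):
            raise ContractError("roi_labels and samples must have equal length")
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ContractError("roi_labels must be unique")
        self.samples = [np.asarray(s, dtype=float).ravel() for s in self.samples]
        for label, s in zip(self.roi_labels, self.samples):
            if s.size < 2:
                raise ContractError(f"ROI {label!r} has fewer than 2 values")

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)


@dataclass
class DensityVector:
    """A KDE-estimated density evaluated on a shared grid.

    Densities are clipped below at a small positive floor and renormalized so
    the cell masses (density x cell width) sum to one.
    """

    grid: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.grid.shape != self.density.shape or self.grid.ndim != 1:
            raise ContractError("grid and density must be 1-D and equal length")
        if np.any(np.diff(self.grid) <= 0):
            raise ContractError("grid must be strictly increasing")
        if np.any(self.density <= 0):
            raise ContractError("density must be strictly positive after flooring")

    def masses(self) -> np.ndarray:
        """Per-cell probability masses (sum to 1)."""
        dx = _grid_dx(self.grid)
        m = self.density * dx
        return m / m.sum()


@dataclass
class ROITimeSeries:
    """ROI x time BOLD signal matrix for one subject."""

    roi_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.roi_labels):
            raise ContractError("values must be an (n_rois, n_timepoints) matrix")
        if self.values.shape[1] < 3:
            raise ContractError("at least 3 time points are required")
        if not np.all(np.isfinite(self.values)):
            raise ContractError("time series contain non-finite values")

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric weighted adjacency over ROIs, zero diagonal, with modality tag.

    ``allow_negative`` exists only for the raw (signed) functional-edge
    convention kept for export; graph metrics reject negative weights.
    """

    roi_labels: list[str]
    weights: np.ndarray
    modality: str
    threshold_info: str | None = None
    allow_negative: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.roi_labels)
        if self.weights.shape != (n, n):
            raise ContractError("weights must be square and match roi_labels")
        if not np.all(np.isfinite(self.weights)):
            raise ContractError("weights must be finite")
        if not np.allclose(self.weights, self.weights.T, atol=1e-10):
            raise ContractError("weights must be symmetric to 1e-10")
        self.weights = (self.weights + self.weights.T) / 2.0
        np.fill_diagonal(self.weights, 0.0)
        if not self.allow_negative and np.any(self.weights < 0):
            raise ContractError("weights must be nonnegative")
        if self.modality not in {"GMN", "WMN", "FBN"}:
            raise ContractError(f"unknown modality {self.modality!r}")

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)

    def edge_count(self) -> int:
        iu = np.triu_indices(self.n_rois, k=1)
        return int(np.count_nonzero(self.weights[iu]))


@dataclass
class ThresholdedNetworkSeries:
    """One weighted network per sparsity level, thresholds strictly increasing."""

    thresholds: np.ndarray
    networks: list[ConnectivityMatrix]

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if len(self.thresholds) != len(self.networks):
            raise ContractError("one network per threshold required")
        if len(self.thresholds) < 2:
            raise ContractError("at least 2 thresholds needed for AUC integration")
        if np.any(np.diff(self.thresholds) <= 0):
            raise ContractError("thresholds must be strictly increasing")


# ---------------------------------------------------------------------------
# KDE densities and KL-based similarity
# ---------------------------------------------------------------------------

def _grid_dx(grid: np.ndarray) -> float:
    dx = np.diff(grid)
    if not np.allclose(dx, dx[0], rtol=1e-8):
        raise ContractError("grid must be uniformly spaced")
    return float(dx[0])


def estimate_pdf(
    values: Sequence[float] | np.ndarray,
    grid: np.ndarray,
    epsilon: float = DENSITY_FLOOR,
) -> DensityVector:
    """Gaussian-kernel density with Silverman's bandwidth on a fixed grid.

    The density is clipped below at ``epsilon`` and renormalized so cell
    masses sum to one; KL divergences between densities on a common grid are
    then always finite.

    Raises
    ------
    DegenerateInputError
        If the values have zero variance (bandwidth would be zero).
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2 or np.ptp(values) == 0:
        raise DegenerateInputError(
            "kernel density estimation requires >= 2 distinct values"
        )
    kde = gaussian_kde(values, bw_method="silverman")
    density = np.clip(kde(np.asarray(grid, dtype=float)), epsilon, None)
    dx = _grid_dx(np.asarray(grid, dtype=float))
    density = density / (density.sum() * dx)
    return DensityVector(grid=np.asarray(grid, dtype=float), density=density)


def _check_shared_grid(p: DensityVector, q: DensityVector) -> None:
    if p.grid.shape != q.grid.shape or not np.allclose(p.grid, q.grid):
        raise ContractError("densities must share a common grid")


def symmetric_kl(p: DensityVector, q: DensityVector) -> float:
    """Symmetrized Kullback-Leibler divergence KL(p||q) + KL(q||p).

    Computed by discrete summation over grid-cell masses with the natural
    logarithm; nonnegative, zero iff the densities agree on the grid.
    """
    _check_shared_grid(p, q)
    mp, mq = p.masses(), q.masses()
    log_ratio = np.log(mp) - np.log(mq)
    return float(np.sum(mp * log_ratio) - np.sum(mq * log_ratio))


def kls(p: DensityVector, q: DensityVector) -> float:
    """KL divergence-based similarity ``exp(-symmetric_kl(p, q))`` in (0, 1]."""
    return float(np.exp(-symmetric_kl(p, q)))


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth as used by ``gaussian_kde``."""
    values = np.asarray(values, dtype=float).ravel()
    n = values.size
    factor = (3.0 * n / 4.0) ** (-1.0 / 5.0)
    return factor * values.std(ddof=1)


def _kde_masses_vectorized(
    values: np.ndarray, grid: np.ndarray, epsilon: float
) -> np.ndarray:
    """Row-wise Gaussian-KDE cell masses; numerically equal to estimate_pdf.

    ``values`` is (n_rois, n_voxels) with every row's bandwidth from
    Silverman's rule, matching ``gaussian_kde(..., bw_method='silverman')``.
    """
    n_rois, n_voxels = values.shape
    h = (3.0 * n_voxels / 4.0) ** (-1.0 / 5.0) * values.std(axis=1, ddof=1)
    z = (grid[None, None, :] - values[:, :, None]) / h[:, None, None]
    density = np.exp(-0.5 * z**2).sum(axis=1) / (
        n_voxels * h[:, None] * np.sqrt(2.0 * np.pi)
    )
    density = np.clip(density, epsilon, None)
    return density / density.sum(axis=1, keepdims=True)


def build_gmn(
    samples: RegionalSampleSet,
    grid_size: int = DEFAULT_GRID_SIZE,
    epsilon: float = DENSITY_FLOOR,
) -> ConnectivityMatrix:
    """Gray-matter network: pairwise KLS between per-ROI value densities.

    All ROI densities of a subject are evaluated on one shared uniform grid
    spanning the pooled value range, padded by three pooled bandwidths, so
    pairwise divergences are defined on common support.
    """
    pooled = np.concatenate(samples.samples)
    for label, vals in zip(samples.roi_labels, samples.samples):
        if np.ptp(vals) == 0:
            raise DegenerateInputError(
                f"ROI {label!r} has zero variance; cannot estimate a density"
            )
    pad = GRID_PAD_BANDWIDTHS * silverman_bandwidth(pooled)
    grid = np.linspace(pooled.min() - pad, pooled.max() + pad, grid_size)

    n = samples.n_rois
    masses = np.empty((n, grid_size))
    sizes = {len(v) for v in samples.samples}
    if len(sizes) == 1:
        # equal-sized bags: evaluate every ROI's KDE in one vectorized pass
        values = np.stack(samples.samples)  # (n_rois, n_voxels)
        masses[:] = _kde_masses_vectorized(values, grid, epsilon)
    else:
        for i, vals in enumerate(samples.samples):
            masses[i] = estimate_pdf(vals, grid, epsilon).masses()

    # D[i, j] = sum_k m_i (ln m_i - ln m_j); symmetric KL = D + D.T
    logm = np.log(masses)
    self_term = np.sum(masses * logm, axis=1)
    cross = masses @ logm.T
    d_kl = self_term[:, None] - cross
    weights = np.exp(-(d_kl + d_kl.T))
    np.fill_diagonal(weights, 0.0)
    return ConnectivityMatrix(
        roi_labels=list(samples.roi_labels), weights=weights, modality="GMN"
    )


# ---------------------------------------------------------------------------
# functional and white-matter networks
# ---------------------------------------------------------------------------

def build_fbn(ts: ROITimeSeries, edge: str = "abs") -> ConnectivityMatrix:
    """Functional network from Pearson correlation of ROI time series.

    ``edge="abs"`` (default) takes |r| so weights are nonnegative, as the
    shortest-path metrics require; ``edge="raw"`` keeps signed correlations
    (export/inspection only — metrics reject negative weights).
    """
    if edge not in {"abs", "raw"}:
        raise ContractError(f"edge must be 'abs' or 'raw', got {edge!r}")
    sds = ts.values.std(axis=1)
    if np.any(sds == 0):
        label = ts.roi_labels[int(np.argmax(sds == 0))]
        raise DegenerateInputError(f"ROI {label!r} has a constant time series")
    r = np.corrcoef(ts.values)
    r = np.clip(r, -1.0, 1.0)
    weights = np.abs(r) if edge == "abs" else r
    np.fill_diagonal(weights, 0.0)
    return ConnectivityMatrix(
        roi_labels=list(ts.roi_labels),
        weights=weights,
        modality="FBN",
        allow_negative=(edge == "raw"),
    )


def build_wmn(fibers: ConnectivityMatrix, fn_cutoff: int = 2) -> ConnectivityMatrix:
    """White-matter network: keep fiber counts strictly above ``fn_cutoff``.

    The default cutoff drops edges with two or fewer streamlines (FN > 2).
    """
    w = fibers.weights
    if np.any(w < 0):
        raise ContractError("fiber counts must be nonnegative")
    if not np.allclose(w, np.round(w)):
        raise ContractError("fiber counts must be integer-valued")
    out = np.where(w > fn_cutoff, w, 0.0)
    return ConnectivityMatrix(
        roi_labels=list(fibers.roi_labels),
        weights=out,
        modality="WMN",
        threshold_info=f"FN>{fn_cutoff}",
    )


# ---------------------------------------------------------------------------
# sparsity thresholding
# ---------------------------------------------------------------------------

def apply_sparsity(net: ConnectivityMatrix, s: float) -> ConnectivityMatrix:
    """Retain the ``round(S * n(n-1)/2)`` largest-weight edges, keeping weights.

    Ties at the cutoff weight are broken by ascending (row, column) index so
    that thresholding is deterministic and nested across S.
    """
    if not (0 < s <= 1):
        raise ContractError(f"sparsity S must be in (0, 1], got {s}")
    if np.any(net.weights < 0):
        raise ContractError("sparsity thresholding requires nonnegative weights")
    n = net.n_rois
    rows, cols = np.triu_indices(n, k=1)
    w = net.weights[rows, cols]
    k = int(round(s * len(w)))
    # stable sort on -w keeps ascending (row, col) order within tied weights
    order = np.argsort(-w, kind="stable")
    keep = order[:k]
    out = np.zeros_like(net.weights)
    out[rows[keep], cols[keep]] = w[keep]
    out = out + out.T
    return ConnectivityMatrix(
        roi_labels=list(net.roi_labels),
        weights=out,
        modality=net.modality,
        threshold_info=f"S={s:.2f}",
    )


def sparsity_grid(
    s_min: float = 0.10, s_max: float = 0.40, step: float = 0.01
) -> np.ndarray:
    """Inclusive threshold grid {s_min, s_min+step, ..., s_max}."""
    if not (s_min < s_max):
        raise ContractError("s_min must be strictly below s_max")
    if step <= 0:
        raise ContractError("step must be positive")
    n_steps = int(np.floor((s_max - s_min) / step + 1e-9)) + 1
    thresholds = s_min + step * np.arange(n_steps)
    if len(thresholds) < 2:
        raise ContractError("threshold sweep needs at least 2 thresholds")
    return thresholds


def threshold_sweep(
    net: ConnectivityMatrix,
    s_min: float = 0.10,
    s_max: float = 0.40,
    step: float = 0.01,
) -> ThresholdedNetworkSeries:
    """Sweep proportional thresholds over a dense network (31 levels by default)."""
    thresholds = sparsity_grid(s_min, s_max, step)
    networks = [apply_sparsity(net, float(s)) for s in thresholds]
    return ThresholdedNetworkSeries(thresholds=thresholds, networks=networks)
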