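"""Feature attribution: classifier weights -> top fraction -> subnetworks.

The absolute value of a linear classifier's coefficients quantifies each
feature's contribution. The top 5% of features (``floor(0.05 * n)``) are
mapped through an atlas table assigning every ROI to one of eight
functional subnetworks, and their distribution over subnetworks and over
modalities summarizes where the discriminative signal lives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError

__all__ = [
    "SUBNETWORK_NAMES",
    "AtlasMapping",
    "feature_contributions",
    "top_fraction",
    "subnetwork_distribution",
    "synthetic_block_mapping",
]

#: the eight functional subnetworks of the 268-node atlas
SUBNETWORK_NAMES = (
    "medial frontal",
    "frontoparietal",
    "default mode",
    "subcortical/cerebellum",
    "motor",
    "visual I",
    "visual II",
    "visual association",
)


@dataclass
class AtlasMapping:
    """ROI label -> subnetwork name; every ROI mapped exactly once."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        if not self.mapping:
            raise ContractError("atlas mapping is empty")

    def subnetwork_of(self, roi: str) -> str:
        try:
            return self.mapping[roi]
        except KeyError:
            raise ContractError(f"ROI {roi!r} is not in the atlas mapping") from None

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AtlasMapping":
        """Build from a two-column (roi_label, subnetwork) table."""
        cols = list(frame.columns[:2])
        if frame[cols[0]].duplicated().any():
            raise ContractError("atlas mapping assigns some ROI more than once")
        return cls(mapping=dict(zip(frame[cols[0]].astype(str), frame[cols[1]])))


def synthetic_block_mapping(roi_labels: list[str]) -> AtlasMapping:
    """Synthetic stand-in atlas: contiguous blocks of ROIs, one per subnetwork.

    The real 268-ROI-to-subnetwork assignment is not bundled; this block
    mapping exists so subnetwork summaries are testable on synthetic cohorts.
    """
    n = len(roi_labels)
    bounds = np.linspace(0, n, len(SUBNETWORK_NAMES) + 1).astype(int)
    mapping = {}
    for k, name in enumerate(SUBNETWORK_NAMES):
        for i in range(bounds[k], bounds[k + 1]):
            mapping[roi_labels[i]] = name
    return AtlasMapping(mapping=mapping)


def feature_contributions(
    weights: np.ndarray, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Rank features by |weight|, descending; ties broken by feature index.

    ``weights`` is the full-length coefficient vector (eliminated features
    carry 0). Returns a DataFrame with columns (modality, roi, metric,
    weight, rank), sorted by rank.
    """
    if weights is None:
        raise ContractError(
            "model exposes no per-feature coefficients; "
            "use a linear classifier (SVM, LR, LDA) for attribution"
        )
    weights = np.abs(np.asarray(weights, dtype=float))
    if len(weights) != len(annotations):
        raise ContractError("weight vector must match the feature annotations")
    order = np.argsort(-weights, kind="stable")
    out = annotations.iloc[order].reset_index(drop=True).copy()
    out["weight"] = weights[order]
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def top_fraction(contributions: pd.DataFrame, fraction: float = 0.05) -> pd.DataFrame:
    """Keep the ``floor(fraction * n)`` highest-weight features."""
    if not (0 < fraction <= 1):
        raise ContractError(f"fraction must be in (0, 1], got {fraction}")
    k = int(np.floor(fraction * len(contributions)))
    if k == 0:
        raise ContractError(
            f"fraction {fraction} of {len(contributions)} features keeps nothing"
        )
    return contributions.nsmallest(k, "rank").reset_index(drop=True)


def subnetwork_distribution(
    subset: pd.DataFrame, mapping: AtlasMapping
) -> tuple[pd.Series, pd.Series]:
    """Proportions of a feature subset per subnetwork and per modality.

    Both series sum to one; subnetworks absent from the subset get 0.
    """
    if len(subset) == 0:
        raise ContractError("feature subset is empty")
    subnets = subset["roi"].astype(str).map(mapping.subnetwork_of)
    sub_counts = subnets.value_counts()
    sub_props = pd.Series(0.0, index=list(SUBNETWORK_NAMES), name="proportion")
    observed = sub_counts / len(subset)
    for name, value in observed.items():
        if name not in sub_props.index:
            sub_props[name] = 0.0
        sub_props[name] = value
    mod_props = subset["modality"].value_counts() / len(subset)
    mod_props.name = "proportion"
    return sub_props, mod_props
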