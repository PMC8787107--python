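import numpy as np
import pytest

from connectoml import CohortConfig, ConnectivityMatrix, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small two-group cohort shared by pipeline-level tests."""
    config = CohortConfig(
        n_rois=8,
        n_subjects_per_group=6,
        n_voxels_per_roi=60,
        n_timepoints=120,
        affected_rois=(0, 1, 2),
        effect_size_gm=1.5,
        effect_size_fc=0.2,
        seed=7,
    )
    return generate_cohort(config)


def make_net(weights, modality="GMN", labels=None):
    weights = np.asarray(weights, dtype=float)
    n = weights.shape[0]
    labels = labels or [chr(65 + i) for i in range(n)]
    return ConnectivityMatrix(roi_labels=labels, weights=weights, modality=modality)


@pytest.fixture
def path_abc():
    """Unit-weight path A-B-C."""
    return make_net([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
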