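import numpy as np
import pytest

from msihetero.preprocessing import tic_normalize
from msihetero.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Well-separated cohort with planted 4-subpopulation structure."""
    cfg = CohortConfig(
        n_patients=10,
        grid_shape=(12, 12),
        n_channels=80,
        k_true=4,
        signature_effect=4.0,
        noise_cv=0.1,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def normalized_cubes(cohort):
    return [tic_normalize(c) for c in cohort.datacubes]


@pytest.fixture(scope="session")
def pooled_truth(cohort, normalized_cubes):
    """(pooled intensity matrix, pooled truth labels) in patient-id order."""
    cubes = sorted(normalized_cubes, key=lambda c: c.patient_id)
    X = np.vstack([c.intensities for c in cubes])
    labels = np.concatenate([cohort.truth_labels[c.patient_id] for c in cubes])
    return X, labels
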