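import numpy as np
import pandas as pd
import pytest

from csfmarkers import CohortSpec, generate_cohort, generate_pvs_phantom
from csfmarkers.stats import center_age

#: scales and threshold used throughout the phantom-recovery tests
#: (1 mm phantom voxels, tube radii around 2 mm)
PHANTOM_SIGMAS = (1.0, 1.4, 2.0)
PHANTOM_PERCENTILE = 30.0


@pytest.fixture(scope="session")
def phantom():
    """One noise-free default phantom: (t1, t2, atlas, truth)."""
    return generate_pvs_phantom(seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """Null cohort of the default study design, age-centered."""
    return center_age(generate_cohort(CohortSpec(seed=42)))


@pytest.fixture()
def tiny_design():
    """Six-subject design table for exhaustive permutation tests."""
    table = pd.DataFrame(
        {
            "group": [0, 0, 0, 1, 1, 1],
            "age": [40.0, 50.0, 60.0, 45.0, 55.0, 65.0],
        }
    )
    return center_age(table)


def design_matrix(table: pd.DataFrame) -> np.ndarray:
    """Full three-term design matrix, independent of the implementation."""
    g = table["group"].to_numpy(float)
    a = table["age_centered"].to_numpy(float)
    return np.column_stack([np.ones_like(g), g, a, g * a])
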