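import numpy as np
import pandas as pd
import pytest

from radrepeat.cohort import CohortSpec, generate_cohort
from radrepeat.model import StandardisedData


def make_table(pairs: dict[str, list[tuple[float, float]]],
               feature: str = "feature") -> pd.DataFrame:
    """Build a long-format table from {patient: [(x1, x2), ...]}."""
    rows = []
    for pid, lesions in pairs.items():
        for j, (x1, x2) in enumerate(lesions):
            lid = f"{pid}-L{j + 1}"
            rows.append((pid, lid, 1, feature, float(x1)))
            rows.append((pid, lid, 2, feature, float(x2)))
    return pd.DataFrame(
        rows, columns=["patient_id", "lesion_id", "repeat", "feature_name", "value"]
    )


@pytest.fixture
def micro_table() -> pd.DataFrame:
    """Two patients, three lesions: the hand-worked initialisation example."""
    return make_table({"P1": [(1, 3), (2, 4)], "P2": [(5, 7)]})


@pytest.fixture
def micro_data() -> StandardisedData:
    """The same micro dataset presented on its raw scale (no standardisation),
    so moment formulas can be checked against hand arithmetic."""
    return StandardisedData(
        feature="feature",
        patient_ids=["P1", "P2"],
        lesion_ids=["P1-L1", "P1-L2", "P2-L1"],
        patient_index=np.array([0, 0, 1]),
        x1=np.array([1.0, 2.0, 5.0]),
        x2=np.array([3.0, 4.0, 7.0]),
        baseline1_mean=0.0,
        baseline1_var=1.0,
    )


@pytest.fixture(scope="session")
def recovery_cohort() -> pd.DataFrame:
    """Balanced cohort at the reference simulation conditions."""
    spec = CohortSpec(
        n_patients=10, lesions_per_patient=[8] * 10,
        mu0=2.0, sigma0=0.5, sigma_p=0.3, sigma_r=0.1, seed=42,
    )
    return generate_cohort(spec)
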