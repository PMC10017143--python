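import numpy as np
import pandas as pd
import pytest

from rxpatterns.synthetic import (
    CohortSpec,
    PlantedFactorSpec,
    block_loadings,
    default_truth,
    generate_dataset,
)
from rxpatterns.windows import DEFAULT_WINDOWS, build_matrix


@pytest.fixture(scope="session")
def small_dataset():
    """One fully generated synthetic extract (n=2000) with planted 3-factor
    oblique structure, shared across tests that only read it."""
    spec = CohortSpec(n_patients=2000, seed=3)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def period1_matrix(small_dataset):
    ds = small_dataset
    return build_matrix(ds.med_events, ds.patients, DEFAULT_WINDOWS[0])


@pytest.fixture(scope="session")
def planted_spec():
    lam, phi, codes = block_loadings(n_factors=3, meds_per_factor=10, salient=0.8, phi_offdiag=0.3)
    return PlantedFactorSpec(
        period_index=1,
        medication_codes=codes,
        loadings=lam,
        factor_correlations=phi,
        marginal_prevalence=np.full(len(codes), 0.15),
    )


@pytest.fixture
def toy_patients():
    """Three patients with known demographics and index dates."""
    return pd.DataFrame(
        {
            "patient_id": ["A", "B", "C"],
            "gender": ["F", "M", "F"],
            "date_of_birth": pd.to_datetime(["1940-03-15", "1950-06-01", "1935-12-31"]),
            "diagnosis_date": pd.to_datetime(["2010-03-14", "2010-01-01", "2012-06-30"]),
            "history_years": [20.0, 20.0, 20.0],
        }
    )
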