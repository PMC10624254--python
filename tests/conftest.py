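import numpy as np
import pandas as pd
import pytest

from voxdosim.tissues import TissueTable, default_tissue_table

COLUMNS = [
    "tissue", "is_liquid", "density_kg_m3", "heat_capacity_J_kg_C",
    "thermal_conductivity_W_m_C", "metabolic_rate_W_kg",
    "permittivity_ratio", "permittivity_child",
    "conductivity_ratio", "conductivity_child_S_m",
    "perfusion_ratio", "perfusion_child_ml_min_kg",
]


def make_table(rows) -> TissueTable:
    """Build a small TissueTable from raw row tuples (test helper)."""
    return TissueTable(pd.DataFrame(rows, columns=COLUMNS))


@pytest.fixture(scope="session")
def tissue_table() -> TissueTable:
    return default_tissue_table()


@pytest.fixture(scope="session")
def uniform_tissue() -> TissueTable:
    # single generic perfused soft tissue: rho=1000, c=3600, k=0.5, Q=1,
    # W=60 ml/min/kg  => omega = 1e-3 1/s
    return make_table([
        ("Tissue", 0, 1000.0, 3600.0, 0.5, 1.0, 1.0, 50.0, 1.0, 0.5, 1.0, 60.0),
    ])


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
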