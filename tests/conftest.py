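import numpy as np
import pandas as pd
import pytest

from iwqi.core import DEFAULT_CATALOG, SampleTable, StandardsTable, validate_sample_table
from iwqi.synthetic import GeneratorConfig, generate, table3_marginals
from iwqi.weighting import LiteratureWeightDB

PARAMS = list(DEFAULT_CATALOG.parameters)


def make_table(values: np.ndarray, season: str = "dry") -> SampleTable:
    """SampleTable over the full 14-parameter catalog from a raw matrix."""
    values = np.asarray(values, dtype=float)
    data = pd.DataFrame(values, columns=PARAMS,
                        index=[f"S{i+1:02d}" for i in range(len(values))])
    table = SampleTable(data, pd.Series(season, index=data.index, name="season"))
    return validate_sample_table(table)


def proportional_table(factors, standards: StandardsTable, season: str = "dry") -> SampleTable:
    """Table where every sample i has Q_ij = 100 * factors[i] for all j."""
    rows = []
    for f in factors:
        row = []
        for p in PARAMS:
            st = standards[p]
            if p == "pH":
                row.append(7.0 + 1.5 * f)
            else:
                row.append(f * st.T)
        rows.append(row)
    return make_table(np.array(rows), season)


@pytest.fixture(scope="session")
def standards() -> StandardsTable:
    return StandardsTable.default()


@pytest.fixture(scope="session")
def weight_db() -> LiteratureWeightDB:
    return LiteratureWeightDB.packaged()


@pytest.fixture(scope="session")
def dry_table() -> SampleTable:
    dry, _ = table3_marginals()
    return generate(dry, GeneratorConfig(n_samples=28, seed=11))


@pytest.fixture(scope="session")
def wet_table() -> SampleTable:
    _, wet = table3_marginals()
    return generate(wet, GeneratorConfig(n_samples=28, seed=12))
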