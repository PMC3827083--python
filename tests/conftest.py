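import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mirxplat.hybrid_thermo import NearestNeighborTable, ThermoConditions
from mirxplat.normalize import ExpressionMatrix
from mirxplat.seqlib import load_probe_panel


@pytest.fixture(scope="session")
def panel():
    """The packaged 12-assay miRNA/probe panel."""
    return load_probe_panel()


@pytest.fixture(scope="session")
def panel_by_name(panel):
    return {e.mirna.name: e for e in panel}


@pytest.fixture(scope="session")
def nn():
    return NearestNeighborTable.default()


@pytest.fixture(scope="session")
def cond():
    return ThermoConditions()


@pytest.fixture
def small_matrix():
    """4 miRNAs x 4 samples in two groups, hand-set values."""
    values = pd.DataFrame(
        {
            "g1_1": [10.0, 100.0, 1.0, 55.0],
            "g1_2": [12.0, 110.0, 2.0, 50.0],
            "g2_1": [11.0, 95.0, 1.5, 60.0],
            "g2_2": [9.0, 105.0, 2.5, 52.0],
        },
        index=["mirA", "mirB", "mirC", "mirD"],
    )
    meta = pd.DataFrame(
        {"group": ["g1", "g1", "g2", "g2"], "platform": ["A"] * 4},
        index=["g1_1", "g1_2", "g2_1", "g2_2"],
    )
    return ExpressionMatrix(values=values, sample_meta=meta)


def random_matrix(rng, n_rows=None, n_cols=None, positive=True):
    n_rows = n_rows or rng.integers(3, 30)
    n_cols = n_cols or rng.integers(2, 8)
    vals = rng.lognormal(5.0, 1.0, size=(n_rows, n_cols)) if positive else rng.normal(
        0.0, 10.0, size=(n_rows, n_cols)
    )
    values = pd.DataFrame(
        vals,
        index=[f"m{i}" for i in range(n_rows)],
        columns=[f"s{j}" for j in range(n_cols)],
    )
    meta = pd.DataFrame(
        {"group": ["g"] * n_cols, "platform": ["A"] * n_cols}, index=values.columns
    )
    return ExpressionMatrix(values=values, sample_meta=meta)
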