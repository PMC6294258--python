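import numpy as np
import pandas as pd
import pytest

from metabodysreg.io import PathwayDB, SampleSheet


@pytest.fixture
def tiny_expr() -> pd.DataFrame:
    """4 genes x 6 samples, strictly positive, easy to reason about."""
    rng = np.random.default_rng(1234)
    values = rng.integers(10, 500, size=(4, 6)).astype(float)
    return pd.DataFrame(values,
                        index=pd.Index(["G1", "G2", "G3", "G4"], name="gene_id"),
                        columns=[f"S{i}" for i in range(1, 7)])


@pytest.fixture
def tiny_sheet() -> SampleSheet:
    frame = pd.DataFrame(
        {
            "condition": ["tumor", "tumor", "tumor", "normal", "normal", "normal"],
            "cohort": "COH",
        },
        index=pd.Index([f"S{i}" for i in range(1, 7)], name="sample_id"),
    )
    return SampleSheet(frame)


@pytest.fixture
def toy_deg() -> pd.DataFrame:
    """Hand-set DEG table used across scoring/direction tests."""
    return pd.DataFrame(
        {
            "log_fc": [1.0, -1.0, 2.0, 0.0, -2.0],
            "t_stat": [3.0, -3.0, 2.0, 0.0, -4.0],
            "p_value": [0.001, 0.002, 0.15, 0.9, 0.0005],
            "adj_p_value": [0.01, 0.01, 0.2, 1.0, 0.01],
            "mean_expr": [8.0, 7.0, 6.0, 5.0, 9.0],
        },
        index=pd.Index(["A", "B", "C", "D", "E"], name="gene_id"),
    )


@pytest.fixture
def toy_db() -> PathwayDB:
    return PathwayDB({"PW1": ["A", "B", "C"], "PW2": ["D", "E"], "PW3": ["X", "Y"]})
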