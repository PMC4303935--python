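import numpy as np
import pandas as pd
import pytest

from exprdrift.io import ExpressionMatrix, SampleMetadata


def make_matrix(values: dict[str, list[float]], genes=None) -> ExpressionMatrix:
    """Small expression matrix from a sample_id -> values mapping."""
    n = len(next(iter(values.values())))
    genes = genes or [f"g{i}" for i in range(n)]
    return ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), dtype=float)
    )


def make_metadata(groups: dict[str, str], survival: dict[str, float] | None = None
                  ) -> SampleMetadata:
    tab = pd.DataFrame({"group": pd.Series(groups)})
    tab.index.name = "sample_id"
    if survival is not None:
        tab["survival_days"] = pd.Series(survival, dtype=float)
    return SampleMetadata(tab)


@pytest.fixture
def toy_two_groups():
    """Two 2-gene groups with obvious centroids (1,1) and (5,3)."""
    matrix = make_matrix({
        "n1": [0.0, 0.0], "n2": [2.0, 2.0],
        "t1": [4.0, 2.0], "t2": [6.0, 4.0],
    })
    meta = make_metadata({"n1": "normal", "n2": "normal",
                          "t1": "tumor", "t2": "tumor"})
    return matrix, meta


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
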