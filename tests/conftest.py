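import numpy as np
import pandas as pd
import pytest

from icisig.cohort_io import ExpressionMatrix


@pytest.fixture
def toy_counts() -> ExpressionMatrix:
    """4-gene x 4-sample integer counts matrix."""
    data = pd.DataFrame(
        [[10, 20, 30, 40], [1, 1, 1, 0], [5, 0, 0, 0], [100, 200, 150, 120]],
        index=["Acta2", "Pdgfrb", "Rare1", "Col1a1"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(data, "counts")


@pytest.fixture
def random_counts() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        rng.poisson(50, size=(30, 8)),
        index=[f"g{i}" for i in range(30)],
        columns=[f"s{i}" for i in range(8)],
    )
    return ExpressionMatrix(data, "counts")


def make_de_table(rows: dict) -> pd.DataFrame:
    """Build a DE-results frame from {gene: (log2fc, p_value)}."""
    df = pd.DataFrame(
        {
            "log2fc": {g: v[0] for g, v in rows.items()},
            "p_value": {g: v[1] for g, v in rows.items()},
        }
    )
    df.index.name = "gene_id"
    df["mean_expression"] = 10.0
    df["q_value"] = df["p_value"]
    return df
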