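import numpy as np
import pandas as pd
import pytest

from rewirenet.io import CountMatrix, FeatureAnnotation, Layer, SampleTable


@pytest.fixture
def tiny_counts() -> CountMatrix:
    df = pd.DataFrame(
        {"s1": [5, 2, 0], "s2": [0, 7, 0]},
        index=["g1", "g2", "g3"],
    )
    return CountMatrix(df, Layer.MRNA)


@pytest.fixture
def three_group_samples() -> SampleTable:
    rows = []
    for g, n in (("AI_PREG", 6), ("NB_PREG", 6), ("NON_PREG", 5)):
        for i in range(n):
            rows.append({"sample_id": f"{g.lower()}_{i}", "outcome": g, "year": 1})
    return SampleTable(pd.DataFrame(rows).set_index("sample_id"))


@pytest.fixture
def annotation() -> FeatureAnnotation:
    df = pd.DataFrame(
        {
            "feature_id": ["g1", "g2", "g3"],
            "biotype": ["protein_coding", "lncRNA", "protein_coding"],
            "length_bp": [1000, 2000, 500],
            "symbol": ["A", "B", "C"],
        }
    ).set_index("feature_id")
    return FeatureAnnotation(df)


def nb_counts(rng, mean, dispersion, size):
    """Gamma-Poisson draws with the NB mean/dispersion parameterization."""
    lam = np.broadcast_to(np.asarray(mean, dtype=float), size)
    if dispersion < 1e-12:
        return rng.poisson(lam)
    mix = rng.gamma(1.0 / dispersion, dispersion * lam)
    return rng.poisson(mix)
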