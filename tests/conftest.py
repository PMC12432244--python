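import numpy as np
import pandas as pd
import pytest

from radsense import synthio
from radsense.datatypes import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts():
    em, truth = synthio.gen_counts(200, 6, 6, deg_fraction=0.1, seed=42)
    return em, truth


@pytest.fixture
def log2cpm_pair():
    """Two log2-scale expression matrices with 20 vs 20 samples."""
    rng = np.random.default_rng(7)
    genes = [f"G{i:03d}" for i in range(50)]
    t = pd.DataFrame(rng.normal(5, 1, (50, 20)), index=genes,
                     columns=[f"t{i}" for i in range(20)])
    n = pd.DataFrame(rng.normal(5, 1, (50, 20)), index=genes,
                     columns=[f"n{i}" for i in range(20)])
    tumor = ExpressionMatrix(t, {c: "tumor" for c in t.columns}, units="log2cpm")
    normal = ExpressionMatrix(n, {c: "normal" for c in n.columns}, units="log2cpm")
    return tumor, normal
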