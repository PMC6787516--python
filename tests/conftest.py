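import numpy as np
import pandas as pd
import pytest

from coexnet import ExpressionMatrix, TraitTable


def make_expr(x: np.ndarray, prefix: str = "g") -> ExpressionMatrix:
    """Wrap a raw array as an ExpressionMatrix with generated ids."""
    g, n = x.shape
    return ExpressionMatrix(pd.DataFrame(
        x,
        index=[f"{prefix}{i+1:04d}" for i in range(g)],
        columns=[f"s{j+1:03d}" for j in range(n)],
    ))


def make_group(n1: int, n2: int, labels=("a", "b")) -> pd.Series:
    return pd.Series([labels[0]] * n1 + [labels[1]] * n2,
                     index=[f"s{j+1:03d}" for j in range(n1 + n2)])


@pytest.fixture
def small_dataset():
    """300 genes, 20+20 samples: one 40-gene shared module (loading 0.9)."""
    rng = np.random.default_rng(42)
    n = 40
    z = rng.standard_normal(n)
    x = rng.standard_normal((300, n))
    a = 0.9
    x[:40] = a * z[None, :] + np.sqrt(1 - a * a) * x[:40]
    expr = make_expr(x)
    group = make_group(20, 20)
    traits = TraitTable(traits=pd.DataFrame({"t1": z}, index=group.index),
                        group=group)
    return expr, traits
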