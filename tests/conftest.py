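import warnings

import numpy as np
import pandas as pd
import pytest

from gutsig import bulk

warnings.filterwarnings("ignore", category=FutureWarning)


def make_expr(values: np.ndarray, genes=None, samples=None) -> bulk.LogExpressionMatrix:
    """Wrap a plain array as a LogExpressionMatrix with unit library sizes."""
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"s{i + 1}" for i in range(values.shape[1])]
    return bulk.LogExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        library_sizes=pd.Series(1.0, index=samples),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
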