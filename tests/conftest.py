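import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode


@pytest.fixture
def toy_tree() -> TreeNode:
    # ((A:1,B:1):1,C:2); A and B are sisters, C is the outgroup
    return TreeNode.read(io.StringIO("((A:1,B:1):1,C:2);"))


@pytest.fixture
def toy_table() -> pd.DataFrame:
    return pd.DataFrame(
        {"s1": [5, 3, 0], "s2": [0, 2, 8], "s3": [4, 4, 4]},
        index=["A", "B", "C"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_count_table(rng, n_taxa=20, n_samples=10, depth=500) -> pd.DataFrame:
    """Random multinomial table with heavy-tailed taxon weights."""
    w = rng.lognormal(0, 1.0, n_taxa)
    counts = np.column_stack(
        [rng.multinomial(depth, w / w.sum()) for _ in range(n_samples)]
    )
    return pd.DataFrame(
        counts,
        index=[f"OTU_{i + 1}" for i in range(n_taxa)],
        columns=[f"s{j + 1}" for j in range(n_samples)],
    )
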