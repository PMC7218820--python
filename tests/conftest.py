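import numpy as np
import pandas as pd
import pytest

from ervcoex import CountMatrix, GeneSetCollection, RankedGeneList


@pytest.fixture
def tiny_matrix() -> CountMatrix:
    """3 genes x 2 samples with a single group; the hand-workable case."""
    df = pd.DataFrame(
        [[2, 4], [6, 12], [10, 20]],
        index=["a", "b", "c"],
        columns=["s1", "s2"],
        dtype=float,
    )
    return CountMatrix(df, {"s1": "x", "s2": "x"})


@pytest.fixture
def worked_ranked_list() -> RankedGeneList:
    """The 5-gene list with scores (3, 2, 1, -1, -2) used for ES oracles."""
    return RankedGeneList(
        ("g1", "g2", "g3", "g4", "g5"), np.array([3, 2, 1, -1, -2], dtype=float)
    )


@pytest.fixture
def small_collection() -> GeneSetCollection:
    return GeneSetCollection.from_dict(
        {"S1": ["a", "b"], "S2": ["b", "c", "d"], "S3": ["e", "f", "g", "h"]}
    )


@pytest.fixture
def two_group_matrix() -> CountMatrix:
    """14-sample, 60-gene random matrix with a designated target row."""
    rng = np.random.default_rng(11)
    samples = [f"old_{i}" for i in range(1, 8)] + [f"young_{i}" for i in range(1, 8)]
    genes = [f"g{i:02d}" for i in range(1, 60)] + ["TARGET"]
    values = pd.DataFrame(
        rng.poisson(100, size=(60, 14)).astype(float), index=genes, columns=samples
    )
    groups = {s: ("old" if s.startswith("old") else "young") for s in samples}
    return CountMatrix(values, groups)
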