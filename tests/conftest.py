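import numpy as np
import pandas as pd
import pytest

from sganvi.feature_pipeline import (EVIDENCE_COLUMNS, SCORE_COLUMNS,
                                     FEATURE_COLUMNS, EncodedMatrix)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_raw_table(n: int, rng: np.random.Generator,
                   missing_rate: float = 0.0,
                   labels: list[str] | None = None) -> pd.DataFrame:
    """A valid raw feature table with random contents."""
    evidence = rng.choice([-1, 0, 1, 2], size=(n, len(EVIDENCE_COLUMNS))).astype(float)
    scores = rng.normal(0.0, 2.0, (n, len(SCORE_COLUMNS)))
    block = np.hstack([evidence, scores])
    if missing_rate > 0:
        mask = rng.random(block.shape) < missing_rate
        block[mask] = np.nan
    df = pd.DataFrame(block, columns=list(FEATURE_COLUMNS))
    df.insert(0, "variant_id", [f"v{i}" for i in range(n)])
    if labels is None:
        labels = rng.choice(["benign", "oncogenic"], size=n).tolist()
    df.insert(1, "label", labels)
    return df


def make_encoded(n: int, dim: int, rng: np.random.Generator,
                 labels=None) -> EncodedMatrix:
    """A bare encoded matrix (values already in [0, 1])."""
    if labels is None:
        labels = [("benign", "oncogenic")[i % 2] for i in range(n)]
    cols = [f"col{i}" for i in range(dim)]
    blocks = np.array(["score"] * dim)
    return EncodedMatrix(
        matrix=rng.random((n, dim)), columns=cols, blocks=blocks,
        labels=np.asarray(labels, dtype=object),
        variant_ids=np.array([f"v{i}" for i in range(n)], dtype=object))


@pytest.fixture
def raw_table(rng):
    return make_raw_table(50, rng, missing_rate=0.05)


def two_cluster_encoded(n_per_class: int, dim: int, sep: float,
                        rng: np.random.Generator,
                        label_values=("benign", "oncogenic")):
    """Two linearly separable Gaussian blobs squashed into [0, 1]."""
    a = rng.normal(0.35, 0.05, (n_per_class, dim))
    b = rng.normal(0.35 + sep, 0.05, (n_per_class, dim))
    x = np.clip(np.vstack([a, b]), 0, 1)
    labels = np.array([label_values[0]] * n_per_class
                      + [label_values[1]] * n_per_class, dtype=object)
    perm = rng.permutation(2 * n_per_class)
    cols = [f"col{i}" for i in range(dim)]
    return EncodedMatrix(matrix=x[perm], columns=cols,
                         blocks=np.array(["score"] * dim),
                         labels=labels[perm],
                         variant_ids=np.array([f"v{i}" for i in range(2 * n_per_class)],
                                              dtype=object))
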