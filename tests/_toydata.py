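"""Shared toy fixture: a 57-column matrix with planted class signal."""

import numpy as np
import pandas as pd

from funlnc.classifier import LabeledSet
from funlnc.features import FeatureMatrix, default_schema


def toy_matrix(n=40, n_informative=2, seed=0, noise=0.3):
    """57-column matrix in which only the first columns separate the classes."""
    rng = np.random.default_rng(seed)
    schema = default_schema()
    ids = [f"l{i}" for i in range(n)]
    y = np.array([1] * (n // 2) + [0] * (n - n // 2))
    data = rng.normal(0, 1, size=(n, 57))
    for j in range(n_informative):
        data[:, j] += y * 3.0 + rng.normal(0, noise, size=n)
    df = pd.DataFrame(data, index=pd.Index(ids, name="lncrna_id"), columns=schema.names)
    labeled = LabeledSet(
        tuple(i for i, l in zip(ids, y) if l), tuple(i for i, l in zip(ids, y) if not l)
    )
    return FeatureMatrix(df, schema), labeled
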