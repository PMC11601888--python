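"""Random Permutation Score: empirical -log10 exceedance of the observed
prediction probability against predictions on column-permuted feature
matrices, and the >2 high-confidence call.

Each permutation shuffles every feature column independently across rows,
so per-feature marginals are preserved exactly while the joint structure is
destroyed. Ties (observed probability equal to a permuted probability) do
NOT count as exceedances.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import PredictionRecord, TrainedModel
from .features import FeatureMatrix

__all__ = [
    "permute_matrix",
    "random_probabilities",
    "exceedance_count",
    "score",
    "score_records",
    "call_hc",
]


def permute_matrix(
    data: pd.DataFrame, rng: np.random.Generator | int
) -> pd.DataFrame:
    """Shuffle each column independently across rows; index preserved."""
    if data.shape[0] == 0:
        raise ValueError("cannot permute an empty matrix")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = data.copy()
    n = len(out)
    for col in out.columns:
        out[col] = out[col].to_numpy()[rng.permutation(n)]
    return out


def random_probabilities(
    model: TrainedModel,
    matrix: FeatureMatrix,
    B: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """n x B matrix; column k holds predictions on the k-th permuted matrix."""
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(matrix.data)
    r = np.empty((n, B), dtype=float)
    for k in range(B):
        permuted = permute_matrix(matrix.data, rng)
        r[:, k] = model.predict_proba(permuted).to_numpy()
    return r


def exceedance_count(p_i: float, r_i: Sequence[float]) -> int:
    """Number of permuted probabilities STRICTLY exceeding the observed one."""
    return int(np.sum(np.asarray(r_i, dtype=float) > p_i))


def score(p_i: float, r_i: Sequence[float], mode: str = "safe") -> float:
    """-log10 empirical exceedance probability of the observed prediction.

    raw mode: -log10(c / B), +inf at c = 0. safe mode (default):
    -log10((c + 1) / (B + 1)), always finite.
    """
    if not 0 <= p_i <= 1:
        raise ValueError(f"probability must be in [0, 1], got {p_i}")
    r_i = np.asarray(r_i, dtype=float)
    if r_i.size < 1:
        raise ValueError("need at least one permuted probability")
    c = exceedance_count(p_i, r_i)
    return score_from_count(c, r_i.size, mode)


def score_from_count(c: int, B: int, mode: str = "safe") -> float:
    if not 0 <= c <= B:
        raise ValueError(f"count must be in [0, {B}], got {c}")
    if mode == "raw":
        return math.inf if c == 0 else -math.log10(c / B)
    if mode == "safe":
        return -math.log10((c + 1) / (B + 1))
    raise ValueError(f"unknown mode {mode!r}")


def score_records(
    records: Sequence[PredictionRecord],
    r: np.ndarray,
    mode: str = "safe",
) -> list[PredictionRecord]:
    """Attach scores to prediction records; row i of ``r`` matches record i."""
    if r.shape[0] != len(records):
        raise ValueError("row count of r must equal the number of records")
    out = []
    for i, rec in enumerate(records):
        s = score(rec.probability, r[i], mode)
        out.append(
            PredictionRecord(
                lncrna_id=rec.lncrna_id,
                probability=rec.probability,
                fun_label=rec.fun_label,
                score=s,
                hc_flag=rec.hc_flag,
            )
        )
    return out


def call_hc(
    records: Sequence[PredictionRecord], threshold: float = 2.0
) -> list[PredictionRecord]:
    """Flag records with score strictly above threshold AND a Fun label."""
    out = []
    for rec in records:
        if rec.score is None:
            raise ValueError(f"record {rec.lncrna_id} has no score")
        out.append(
            PredictionRecord(
                lncrna_id=rec.lncrna_id,
                probability=rec.probability,
                fun_label=rec.fun_label,
                score=rec.score,
                hc_flag=bool(rec.score > threshold and rec.fun_label),
            )
        )
    return out


def records_to_frame(records: Sequence[PredictionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lncrna_id": [r.lncrna_id for r in records],
            "probability": [r.probability for r in records],
            "label": ["Fun" if r.fun_label else "Non" for r in records],
            "score": [r.score if r.score is not None else float("nan") for r in records],
            "hc_flag": [int(r.hc_flag) for r in records],
        }
    ).set_index("lncrna_id")
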