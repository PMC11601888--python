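"""Random-forest classification of functional lncRNAs.

Covers the full training protocol: stratified or similarity-grouped
train/test splitting, train-statistics-only standardization with predictor
screening, cross-validated hyperparameter selection, evaluation, category
ablation, label-noise robustness, Gini importances, and per-feature
odds-ratio / relative-risk contribution.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .features import FeatureMatrix, FeatureSchema

__all__ = [
    "LabeledSet",
    "TrainedModel",
    "EvalReport",
    "PredictionRecord",
    "split_random",
    "cluster_by_similarity",
    "split_grouped",
    "preprocess",
    "train_rf",
    "fit_model",
    "predict_and_label",
    "evaluate",
    "ablate_categories",
    "add_label_noise",
    "noise_robustness",
    "importance_scores",
    "feature_contribution",
]


@dataclasses.dataclass(frozen=True)
class LabeledSet:
    positives: tuple[str, ...]
    negatives: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.positives) & set(self.negatives):
            raise ValueError("positive and negative id sets overlap")

    @property
    def ids(self) -> list[str]:
        return list(self.positives) + list(self.negatives)

    def labels(self) -> pd.Series:
        return pd.Series(
            [1] * len(self.positives) + [0] * len(self.negatives), index=self.ids
        )

    def require_in(self, matrix: FeatureMatrix) -> None:
        missing = [i for i in self.ids if i not in matrix.data.index]
        if missing:
            raise KeyError(f"labeled ids absent from feature matrix: {missing[:5]}")


@dataclasses.dataclass
class ScalingState:
    means: dict[str, float]
    sds: dict[str, float]

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        cols = list(self.means)
        out = df[cols].copy().astype(float)
        for c in cols:
            out[c] = (out[c] - self.means[c]) / self.sds[c]
        return out


@dataclasses.dataclass
class TrainedModel:
    forest: RandomForestClassifier
    scaling: ScalingState
    predictors: list[str]
    hyperparameters: dict
    seed: int
    schema: FeatureSchema | None = None

    def predict_proba(self, matrix: FeatureMatrix | pd.DataFrame) -> pd.Series:
        df = matrix.data if isinstance(matrix, FeatureMatrix) else matrix
        x = self.scaling.transform(df[self.predictors])
        probs = self.forest.predict_proba(x.to_numpy())[:, 1]
        return pd.Series(probs, index=df.index)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.forest, outdir / "forest.joblib")
        meta = {
            "predictors": self.predictors,
            "hyperparameters": self.hyperparameters,
            "seed": self.seed,
            "scaling": {"means": self.scaling.means, "sds": self.scaling.sds},
        }
        with open(outdir / "model.json", "w") as fh:
            json.dump(meta, fh, indent=2)
        if self.schema is not None:
            self.schema.to_json(outdir / "schema.json")

    @classmethod
    def load(cls, outdir: str | Path) -> "TrainedModel":
        outdir = Path(outdir)
        forest = joblib.load(outdir / "forest.joblib")
        with open(outdir / "model.json") as fh:
            meta = json.load(fh)
        schema = None
        if (outdir / "schema.json").exists():
            schema = FeatureSchema.from_json(outdir / "schema.json")
        return cls(
            forest=forest,
            scaling=ScalingState(**meta["scaling"]),
            predictors=meta["predictors"],
            hyperparameters=meta["hyperparameters"],
            seed=meta["seed"],
            schema=schema,
        )


@dataclasses.dataclass(frozen=True)
class EvalReport:
    auroc: float
    auprc: float
    precision: float
    recall: float
    threshold: float = 0.5

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class PredictionRecord:
    lncrna_id: str
    probability: float
    fun_label: bool
    score: float | None = None
    hc_flag: bool = False


# ---------------------------------------------------------------------------
# splitting


def split_random(
    labeled: LabeledSet, train_frac: float = 0.8, seed: int = 0
) -> tuple[LabeledSet, LabeledSet]:
    """Class-stratified random split; per class |train| = round(frac * n)."""
    if not 0 < train_frac <= 1:
        raise ValueError("train_frac must be in (0, 1]")
    rng = np.random.default_rng(seed)
    parts: dict[str, tuple[list[str], list[str]]] = {}
    for side, ids in (("pos", labeled.positives), ("neg", labeled.negatives)):
        ids = list(ids)
        order = rng.permutation(len(ids))
        n_train = round(train_frac * len(ids))
        train = [ids[i] for i in order[:n_train]]
        test = [ids[i] for i in order[n_train:]]
        parts[side] = (train, test)
    if train_frac == 1.0:
        warnings.warn("train_frac=1.0 leaves an empty test set", stacklevel=2)
    train = LabeledSet(tuple(parts["pos"][0]), tuple(parts["neg"][0]))
    test = LabeledSet(tuple(parts["pos"][1]), tuple(parts["neg"][1]))
    return train, test


def _kmer_set(seq: str, k: int) -> frozenset[str]:
    seq = seq.upper()
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def cluster_by_similarity(
    sequences: Mapping[str, str], k: int = 8, threshold: float = 0.3
) -> dict[str, int]:
    """Single-linkage clusters over pairwise k-mer Jaccard similarity.

    Two sequences join the same cluster when their k-mer Jaccard similarity
    is >= ``threshold`` (directly or transitively). Returns id -> cluster
    index (dense, ordered by first member).
    """
    missing = [i for i, s in sequences.items() if not s]
    if missing:
        raise ValueError(f"missing sequences for ids: {missing}")
    ids = list(sequences)
    kmers = {i: _kmer_set(sequences[i], k) for i in ids}
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a_idx, a in enumerate(ids):
        for b in ids[a_idx + 1 :]:
            ka, kb = kmers[a], kmers[b]
            union = len(ka | kb)
            jac = len(ka & kb) / union if union else 1.0
            if jac >= threshold:
                parent[find(a)] = find(b)

    roots: dict[str, int] = {}
    out: dict[str, int] = {}
    for i in ids:
        r = find(i)
        if r not in roots:
            roots[r] = len(roots)
        out[i] = roots[r]
    return out


def split_grouped(
    labeled: LabeledSet,
    clusters: Mapping[str, int],
    train_frac: float = 0.8,
    seed: int = 0,
) -> tuple[LabeledSet, LabeledSet]:
    """Assign whole similarity clusters to train or test; zero leakage.

    Clusters are visited in seed-shuffled order and moved to the test side
    while it has room for them, so the achieved split approaches the target
    without ever splitting a cluster.
    """
    if not 0 < train_frac <= 1:
        raise ValueError("train_frac must be in (0, 1]")
    ids = labeled.ids
    missing = [i for i in ids if i not in clusters]
    if missing:
        raise ValueError(f"ids without cluster assignment: {missing[:5]}")
    members: dict[int, list[str]] = {}
    for i in ids:
        members.setdefault(clusters[i], []).append(i)
    rng = np.random.default_rng(seed)
    order = rng.permutation(sorted(members))
    target_test = round((1 - train_frac) * len(ids))
    test_ids: set[str] = set()
    for c in order:
        size = len(members[c])
        if len(test_ids) + size <= target_test:
            test_ids.update(members[c])
    achieved = 1 - len(test_ids) / len(ids) if ids else 1.0
    if abs(achieved - train_frac) > 0.05:
        warnings.warn(
            f"grouped split achieved train fraction {achieved:.2f} "
            f"(target {train_frac:.2f})",
            stacklevel=2,
        )
    pos_train = tuple(i for i in labeled.positives if i not in test_ids)
    pos_test = tuple(i for i in labeled.positives if i in test_ids)
    neg_train = tuple(i for i in labeled.negatives if i not in test_ids)
    neg_test = tuple(i for i in labeled.negatives if i in test_ids)
    return LabeledSet(pos_train, neg_train), LabeledSet(pos_test, neg_test)


# ---------------------------------------------------------------------------
# preprocessing + training


def preprocess(
    matrix: FeatureMatrix,
    train_ids: Sequence[str],
    corr_cutoff: float = 0.95,
) -> tuple[pd.DataFrame, ScalingState, list[str]]:
    """Standardize by train statistics and screen predictors.

    Zero-variance columns (on train) are dropped; from every pair with
    |Pearson r| > ``corr_cutoff`` on train, the member with the larger mean
    absolute correlation is removed. The returned frame covers ALL rows of
    the matrix, transformed with train-set statistics only.
    """
    train = matrix.data.loc[list(train_ids)].astype(float)
    sds = train.std(ddof=1)
    keep = [c for c in train.columns if sds[c] > 0 and np.isfinite(sds[c])]
    if len(train_ids) < 2:
        raise ValueError("need at least 2 training rows")

    corr = train[keep].corr().abs()
    np.fill_diagonal(corr.values, 0.0)
    while True:
        max_val = corr.values.max() if len(corr) else 0.0
        if max_val <= corr_cutoff:
            break
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        a, b = corr.columns[i], corr.columns[j]
        drop = a if corr[a].mean() >= corr[b].mean() else b
        corr = corr.drop(index=drop, columns=drop)
    selected = [c for c in keep if c in set(corr.columns)]

    means = {c: float(train[c].mean()) for c in selected}
    scale = {c: float(train[c].std(ddof=1)) for c in selected}
    state = ScalingState(means, scale)
    return state.transform(matrix.data), state, selected


def train_rf(
    train_matrix: pd.DataFrame,
    labels: pd.Series,
    cv_folds: int = 10,
    seed: int = 0,
    n_trees: int = 500,
    mtry_grid: Sequence[float | str] | None = None,
) -> tuple[RandomForestClassifier, dict]:
    """Fit the forest, tuning candidate-predictors-per-split by CV AUROC.

    ``train_matrix`` must already be preprocessed (selected + scaled
    columns). Returns the refitted forest and the chosen hyperparameters.
    """
    x = train_matrix.to_numpy()
    y = labels.loc[train_matrix.index].to_numpy()
    n_features = x.shape[1]
    if mtry_grid is None:
        candidates = sorted({
            max(1, int(round(np.sqrt(n_features)))),
            max(1, n_features // 4),
            max(1, n_features // 2),
        })
    else:
        candidates = list(mtry_grid)

    best_mtry, best_score = candidates[0], -np.inf
    n_per_class = min(int((y == 1).sum()), int((y == 0).sum()))
    folds = max(2, min(cv_folds, n_per_class))
    for mtry in candidates:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        scores = []
        for tr, va in skf.split(x, y):
            rf = RandomForestClassifier(
                n_estimators=n_trees, max_features=mtry, random_state=seed, n_jobs=1
            )
            rf.fit(x[tr], y[tr])
            p = rf.predict_proba(x[va])[:, 1]
            if len(np.unique(y[va])) == 2:
                scores.append(roc_auc_score(y[va], p))
        mean_score = float(np.mean(scores)) if scores else 0.0
        if mean_score > best_score:
            best_score, best_mtry = mean_score, mtry

    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features=best_mtry, random_state=seed, n_jobs=1
    )
    forest.fit(x, y)
    hyper = {
        "n_trees": n_trees,
        "max_features": best_mtry,
        "cv_folds": folds,
        "cv_auroc": best_score,
    }
    return forest, hyper


def fit_model(
    matrix: FeatureMatrix,
    train_set: LabeledSet,
    cv_folds: int = 10,
    seed: int = 0,
    n_trees: int = 500,
    tune: bool = True,
    corr_cutoff: float = 0.95,
) -> TrainedModel:
    """Preprocess on the training ids and train the forest end to end."""
    train_set.require_in(matrix)
    transformed, state, selected = preprocess(matrix, train_set.ids, corr_cutoff)
    labels = train_set.labels()
    train_x = transformed.loc[train_set.ids, selected]
    if tune:
        forest, hyper = train_rf(train_x, labels, cv_folds, seed, n_trees)
    else:
        forest = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed, n_jobs=1
        )
        forest.fit(train_x.to_numpy(), labels.loc[train_x.index].to_numpy())
        hyper = {"n_trees": n_trees, "max_features": "sqrt", "cv_folds": 0}
    # restrict scaling state to the selected predictors
    state = ScalingState(
        {c: state.means[c] for c in selected}, {c: state.sds[c] for c in selected}
    )
    return TrainedModel(
        forest=forest,
        scaling=state,
        predictors=selected,
        hyperparameters=hyper,
        seed=seed,
        schema=matrix.schema,
    )


def predict_and_label(
    model: TrainedModel,
    matrix: FeatureMatrix,
    threshold: float = 0.5,
) -> list[PredictionRecord]:
    """Probability plus Fun/Non label; probability >= threshold means Fun."""
    probs = model.predict_proba(matrix)
    return [
        PredictionRecord(lncrna_id=str(i), probability=float(p), fun_label=p >= threshold)
        for i, p in probs.items()
    ]


def evaluate(
    records: Sequence[PredictionRecord],
    truth: Mapping[str, int],
    threshold: float = 0.5,
) -> EvalReport:
    """AUROC (midrank ties), AUPRC (step integration), precision/recall."""
    y = np.array([truth[r.lncrna_id] for r in records])
    p = np.array([r.probability for r in records])
    pred = p >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    if len(np.unique(y)) < 2:
        raise ValueError("evaluation requires both classes in the truth set")
    return EvalReport(
        auroc=float(roc_auc_score(y, p)),
        auprc=float(average_precision_score(y, p)),
        precision=precision,
        recall=recall,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# protocols from the evaluation section


def ablate_categories(
    matrix: FeatureMatrix,
    labeled: LabeledSet,
    train_frac: float = 0.8,
    seed: int = 0,
    n_trees: int = 200,
    subcategories: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Retrain dropping each feature subcategory; report metric deltas.

    Returns a frame indexed by subcategory with columns
    delta_auroc/delta_auprc/delta_precision/delta_recall relative to the
    full model on the same held-out split.
    """
    schema = matrix.schema
    if subcategories is None:
        subcategories = sorted(schema.subcategory_counts())
    train, test = split_random(labeled, train_frac, seed)
    truth = dict(labeled.labels())

    def run(drop: str | None) -> EvalReport:
        cols = [
            d.name for d in schema.descriptors
            if drop is None or d.subcategory != drop
        ]
        # column-subset view; bypasses the 57-column schema check on purpose
        sub = FeatureMatrix.__new__(FeatureMatrix)
        sub.data = matrix.data[cols]
        sub.schema = schema
        model = fit_model(sub, train, seed=seed, n_trees=n_trees, tune=False)
        recs = [r for r in predict_and_label(model, sub)
                if r.lncrna_id in set(test.ids)]
        return evaluate(recs, truth)

    base = run(None)
    rows = []
    for sub in subcategories:
        rep = run(sub)
        rows.append({
            "subcategory": sub,
            "delta_auroc": rep.auroc - base.auroc,
            "delta_auprc": rep.auprc - base.auprc,
            "delta_precision": rep.precision - base.precision,
            "delta_recall": rep.recall - base.recall,
        })
    return pd.DataFrame(rows).set_index("subcategory")


def add_label_noise(
    labeled: LabeledSet, rate: float, seed: int = 0
) -> tuple[LabeledSet, list[str]]:
    """Flip exactly floor(rate * n) labels, sampled without replacement.

    Returns the noisy set and the flipped ids (audit trail).
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    ids = labeled.ids
    n_flip = int(rate * len(ids))
    rng = np.random.default_rng(seed)
    flipped = set(rng.choice(ids, size=n_flip, replace=False).tolist()) if n_flip else set()
    pos = set(labeled.positives)
    new_pos = (pos - flipped) | (set(labeled.negatives) & flipped)
    new_neg = set(ids) - new_pos
    return (
        LabeledSet(tuple(sorted(new_pos)), tuple(sorted(new_neg))),
        sorted(flipped),
    )


def noise_robustness(
    matrix: FeatureMatrix,
    labeled: LabeledSet,
    rates: Sequence[float] = (0.0, 0.05, 0.10, 0.15),
    iters: int = 100,
    seed: int = 0,
    n_trees: int = 200,
) -> pd.DataFrame:
    """Mean/SD of held-out AUROC/AUPRC per label-noise rate.

    Each iteration flips labels across the whole labeled set (train and
    test), re-splits, retrains with fixed hyperparameters and evaluates
    against the noisy truth.
    """
    rows = []
    for rate in rates:
        aurocs, auprcs = [], []
        for it in range(iters):
            it_seed = seed * 100_003 + it * 7919 + int(rate * 1000)
            noisy, _ = add_label_noise(labeled, rate, it_seed)
            train, test = split_random(noisy, 0.8, it_seed)
            model = fit_model(matrix, train, seed=it_seed, n_trees=n_trees, tune=False)
            recs = [r for r in predict_and_label(model, matrix)
                    if r.lncrna_id in set(test.ids)]
            rep = evaluate(recs, dict(noisy.labels()))
            aurocs.append(rep.auroc)
            auprcs.append(rep.auprc)
        rows.append({
            "rate": rate,
            "mean_auroc": float(np.mean(aurocs)),
            "sd_auroc": float(np.std(aurocs, ddof=1)) if iters > 1 else 0.0,
            "mean_auprc": float(np.mean(auprcs)),
            "sd_auprc": float(np.std(auprcs, ddof=1)) if iters > 1 else 0.0,
        })
    return pd.DataFrame(rows).set_index("rate")


def importance_scores(model: TrainedModel) -> pd.Series:
    """Mean-decrease-Gini importance per selected predictor (all >= 0)."""
    return pd.Series(model.forest.feature_importances_, index=model.predictors)


def feature_contribution(
    matrix: FeatureMatrix, records: Sequence[PredictionRecord]
) -> pd.DataFrame:
    """Odds ratio and relative risk of the predicted label per feature.

    Each feature is dichotomized at its median (value > median = high); the
    2x2 table against the predicted Fun label gives OR = ad/bc and
    RR = [a/(a+b)] / [c/(c+d)], with Haldane's +0.5 per cell when any cell
    is 0.
    """
    ids = [r.lncrna_id for r in records]
    fun = np.array([r.fun_label for r in records])
    df = matrix.data.loc[ids]
    rows = []
    for col in df.columns:
        high = df[col].to_numpy() > float(df[col].median())
        a = float(np.sum(high & fun))
        b = float(np.sum(high & ~fun))
        c = float(np.sum(~high & fun))
        d = float(np.sum(~high & ~fun))
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        odds_ratio = (a * d) / (b * c)
        rr = (a / (a + b)) / (c / (c + d))
        rows.append({"feature": col, "odds_ratio": odds_ratio, "relative_risk": rr})
    return pd.DataFrame(rows).set_index("feature")
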