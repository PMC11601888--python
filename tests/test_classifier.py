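import itertools

import numpy as np
import pandas as pd
import pytest

from funlnc.classifier import (
    LabeledSet,
    PredictionRecord,
    add_label_noise,
    cluster_by_similarity,
    evaluate,
    feature_contribution,
    fit_model,
    importance_scores,
    predict_and_label,
    preprocess,
    split_grouped,
    split_random,
    train_rf,
)
from funlnc.features import FeatureMatrix, default_schema
from _toydata import toy_matrix


class TestSplitRandom:
    def test_counts(self):
        labeled = LabeledSet(tuple(f"p{i}" for i in range(10)),
                             tuple(f"n{i}" for i in range(10)))
        train, test = split_random(labeled, 0.8, seed=1)
        assert len(train.positives) == 8 and len(train.negatives) == 8
        assert len(test.positives) == 2 and len(test.negatives) == 2
        assert set(train.ids) | set(test.ids) == set(labeled.ids)
        assert not set(train.ids) & set(test.ids)

    def test_same_seed_identical(self):
        labeled = LabeledSet(tuple(f"p{i}" for i in range(9)),
                             tuple(f"n{i}" for i in range(7)))
        assert split_random(labeled, 0.8, 3) == split_random(labeled, 0.8, 3)

    def test_full_train_warns(self):
        labeled = LabeledSet(("p1", "p2"), ("n1", "n2"))
        with pytest.warns(UserWarning):
            train, test = split_random(labeled, 1.0, 0)
        assert test.ids == []


class TestClusterBySimilarity:
    def test_identical_sequences_cluster(self):
        seqs = {"a": "ACGTACGTACGT", "b": "ACGTACGTACGT"}
        c = cluster_by_similarity(seqs, k=4)
        assert c["a"] == c["b"]

    def test_disjoint_kmers_separate(self):
        c = cluster_by_similarity({"a": "A" * 20, "b": "C" * 20}, k=4)
        assert c["a"] != c["b"]

    def test_missing_sequence_errors(self):
        with pytest.raises(ValueError, match="b"):
            cluster_by_similarity({"a": "ACGT", "b": ""})

    def test_oracle_all_pairs_components(self):
        rng = np.random.default_rng(11)
        bases = np.array(list("ACGT"))
        seqs = {}
        motifs = ["".join(bases[rng.integers(0, 4, 40)]) for _ in range(6)]
        for i in range(30):
            m = motifs[i % 6]
            extra = "".join(bases[rng.integers(0, 4, 20)])
            seqs[f"s{i}"] = m + extra
        k, thr = 8, 0.3
        got = cluster_by_similarity(seqs, k, thr)

        # independent oracle: explicit all-pairs graph + DFS components
        def kmers(s):
            return {s[i : i + k] for i in range(len(s) - k + 1)}
        ids = list(seqs)
        adj = {i: set() for i in ids}
        for a, b in itertools.combinations(ids, 2):
            ka, kb = kmers(seqs[a]), kmers(seqs[b])
            if len(ka & kb) / len(ka | kb) >= thr:
                adj[a].add(b)
                adj[b].add(a)
        comp, seen = {}, set()
        for i in ids:
            if i in seen:
                continue
            stack, members = [i], []
            while stack:
                x = stack.pop()
                if x in seen:
                    continue
                seen.add(x)
                members.append(x)
                stack.extend(adj[x])
            for m in members:
                comp[m] = i
        for a, b in itertools.combinations(ids, 2):
            assert (got[a] == got[b]) == (comp[a] == comp[b])


class TestSplitGrouped:
    def _labeled(self, n=40):
        return LabeledSet(tuple(f"p{i}" for i in range(n // 2)),
                          tuple(f"n{i}" for i in range(n // 2)))

    def test_singleton_clusters_full_coverage(self):
        labeled = self._labeled(20)
        clusters = {i: j for j, i in enumerate(labeled.ids)}
        train, test = split_grouped(labeled, clusters, 0.8, 0)
        assert set(train.ids) | set(test.ids) == set(labeled.ids)
        assert abs(len(train.ids) - 16) <= 1

    def test_zero_leakage_100_random_configs(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            n = int(rng.integers(10, 60))
            labeled = LabeledSet(tuple(f"p{i}" for i in range(n)),
                                 tuple(f"n{i}" for i in range(n)))
            clusters = {i: int(rng.integers(0, max(2, n // 2))) for i in labeled.ids}
            train, test = split_grouped(labeled, clusters, 0.8, trial)
            train_c = {clusters[i] for i in train.ids}
            test_c = {clusters[i] for i in test.ids}
            assert not train_c & test_c, "cluster leaked across train/test"
            assert set(train.ids) | set(test.ids) == set(labeled.ids)

    def test_giant_cluster_goes_to_train(self):
        labeled = self._labeled(40)
        clusters = {i: 0 for i in labeled.ids}
        for i in list(labeled.ids)[:4]:
            clusters[i] = 1 + hash(i) % 3
        with pytest.warns(UserWarning, match="achieved"):
            train, test = split_grouped(labeled, clusters, 0.8, 0)
        big_members = [i for i in labeled.ids if clusters[i] == 0]
        assert set(big_members) <= set(train.ids)


class TestPreprocess:
    def test_constant_column_dropped(self):
        matrix, labeled = toy_matrix(seed=2)
        matrix.data.iloc[:, 10] = 5.0
        _, _, selected = preprocess(matrix, labeled.ids)
        assert matrix.data.columns[10] not in selected

    def test_duplicate_column_one_dropped(self):
        matrix, labeled = toy_matrix(seed=3)
        matrix.data.iloc[:, 21] = matrix.data.iloc[:, 20]
        _, _, selected = preprocess(matrix, labeled.ids)
        pair = {matrix.data.columns[20], matrix.data.columns[21]}
        assert len(pair & set(selected)) == 1

    def test_train_columns_standardized(self):
        matrix, labeled = toy_matrix(seed=4)
        transformed, state, selected = preprocess(matrix, labeled.ids)
        train = transformed.loc[labeled.ids, selected]
        assert np.allclose(train.mean(), 0, atol=1e-9)
        assert np.allclose(train.std(ddof=1), 1, atol=1e-9)

    def test_test_rows_use_train_statistics(self):
        matrix, labeled = toy_matrix(n=40, seed=5)
        train_ids = labeled.ids[:30]
        transformed, state, selected = preprocess(matrix, train_ids)
        col = selected[0]
        raw = matrix.data.loc["l39", col]
        expect = (raw - state.means[col]) / state.sds[col]
        assert transformed.loc["l39", col] == pytest.approx(expect)


class TestTrainRF:
    def test_separable_cv_auroc_high(self):
        matrix, labeled = toy_matrix(n=60, seed=6, noise=0.1)
        transformed, _, selected = preprocess(matrix, labeled.ids)
        _, hyper = train_rf(transformed[selected], labeled.labels(),
                            cv_folds=5, seed=0, n_trees=100)
        assert hyper["cv_auroc"] > 0.95

    def test_label_permutation_baseline_near_half(self):
        matrix, labeled = toy_matrix(n=120, seed=7)
        rng = np.random.default_rng(0)
        ids = labeled.ids
        perm = rng.permutation(len(ids))
        y = labeled.labels().to_numpy()
        shuffled = pd.Series(y[perm], index=ids)
        pos = tuple(i for i in ids if shuffled[i] == 1)
        neg = tuple(i for i in ids if shuffled[i] == 0)
        transformed, _, selected = preprocess(matrix, ids)
        _, hyper = train_rf(transformed[selected], LabeledSet(pos, neg).labels(),
                            cv_folds=5, seed=0, n_trees=100)
        assert 0.35 <= hyper["cv_auroc"] <= 0.65

    def test_same_seed_reproduces_probabilities(self):
        matrix, labeled = toy_matrix(n=40, seed=8)
        m1 = fit_model(matrix, labeled, cv_folds=3, seed=5, n_trees=50)
        m2 = fit_model(matrix, labeled, cv_folds=3, seed=5, n_trees=50)
        p1 = m1.predict_proba(matrix)
        p2 = m2.predict_proba(matrix)
        pd.testing.assert_series_equal(p1, p2)


class TestPredictAndLabel:
    def _model_matrix(self):
        matrix, labeled = toy_matrix(n=40, seed=9, noise=0.1)
        model = fit_model(matrix, labeled, seed=0, n_trees=50, tune=False)
        return model, matrix

    def test_threshold_tie_is_fun(self):
        rec = PredictionRecord("x", 0.5, True)
        model, matrix = self._model_matrix()
        records = predict_and_label(model, matrix, threshold=0.0)
        assert all(r.fun_label for r in records)  # p >= 0 always

    def test_point_49_is_non(self):
        model, matrix = self._model_matrix()
        for r in predict_and_label(model, matrix, threshold=0.5):
            assert r.fun_label == (r.probability >= 0.5)

    def test_monotone_in_threshold(self):
        model, matrix = self._model_matrix()
        counts = [
            sum(r.fun_label for r in predict_and_label(model, matrix, t))
            for t in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)


def brute_auroc(y, p):
    """Pair-counting AUROC with half credit for ties."""
    pos = [pi for yi, pi in zip(y, p) if yi == 1]
    neg = [pi for yi, pi in zip(y, p) if yi == 0]
    total = wins = 0.0
    for a in pos:
        for b in neg:
            total += 1
            if a > b:
                wins += 1
            elif a == b:
                wins += 0.5
    return wins / total


class TestEvaluate:
    def _records(self, probs):
        return [PredictionRecord(f"l{i}", p, p >= 0.5) for i, p in enumerate(probs)]

    def test_perfect_separation(self):
        recs = self._records([0.9, 0.8, 0.2, 0.1])
        truth = {"l0": 1, "l1": 1, "l2": 0, "l3": 0}
        rep = evaluate(recs, truth)
        assert rep.auroc == 1.0 and rep.auprc == 1.0

    def test_all_equal_probabilities(self):
        recs = self._records([0.5] * 6)
        truth = {f"l{i}": int(i < 3) for i in range(6)}
        assert evaluate(recs, truth).auroc == 0.5

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            n = int(rng.integers(6, 20))
            y = rng.integers(0, 2, n)
            if len(set(y)) < 2:
                y[0], y[1] = 0, 1
            p = np.round(rng.random(n), 2)  # rounded -> ties occur
            recs = [PredictionRecord(f"l{i}", float(p[i]), p[i] >= 0.5)
                    for i in range(n)]
            truth = {f"l{i}": int(y[i]) for i in range(n)}
            assert evaluate(recs, truth).auroc == pytest.approx(brute_auroc(y, p))

    def test_single_class_errors(self):
        recs = self._records([0.4, 0.6])
        with pytest.raises(ValueError):
            evaluate(recs, {"l0": 1, "l1": 1})


class TestAddLabelNoise:
    def _labeled(self, n=100):
        return LabeledSet(tuple(f"p{i}" for i in range(n // 2)),
                          tuple(f"n{i}" for i in range(n // 2)))

    def test_exact_flip_count(self):
        labeled = self._labeled(100)
        noisy, flipped = add_label_noise(labeled, 0.1, seed=0)
        assert len(flipped) == 10
        before = labeled.labels()
        after = noisy.labels()
        changed = [i for i in labeled.ids if before[i] != after[i]]
        assert sorted(changed) == flipped

    def test_rate_zero_identity(self):
        labeled = self._labeled(20)
        noisy, flipped = add_label_noise(labeled, 0.0, seed=0)
        assert flipped == []
        assert set(noisy.positives) == set(labeled.positives)

    def test_floor_rule(self):
        labeled = self._labeled(10)  # n=10, rate .19 -> floor 1 flip
        _, flipped = add_label_noise(labeled, 0.19, seed=1)
        assert len(flipped) == 1


class TestImportanceAndContribution:
    def test_planted_signal_outranks_noise(self):
        matrix, labeled = toy_matrix(n=80, seed=14, n_informative=1, noise=0.1)
        model = fit_model(matrix, labeled, seed=0, n_trees=200, tune=False)
        imp = importance_scores(model)
        assert (imp >= 0).all()
        assert len(imp) == len(model.predictors)
        signal_col = matrix.data.columns[0]
        assert imp[signal_col] == imp.max()

    def test_or_rr_arithmetic(self):
        # a=30, b=10, c=10, d=30 -> OR 9, RR 3
        n = 80
        rng = np.random.default_rng(15)
        schema = default_schema()
        ids = [f"l{i}" for i in range(n)]
        df = pd.DataFrame(rng.normal(size=(n, 57)), index=pd.Index(ids, name="lncrna_id"),
                          columns=schema.names)
        col = schema.names[0]
        # 40 high (values 1..40), 40 low (-40..-1); median 0 between them
        df[col] = np.concatenate([np.arange(1, 41), -np.arange(1, 41)])
        fun = [True] * 30 + [False] * 10 + [True] * 10 + [False] * 30
        records = [PredictionRecord(ids[i], 0.5, fun[i]) for i in range(n)]
        out = feature_contribution(FeatureMatrix(df, schema), records)
        assert out.loc[col, "odds_ratio"] == pytest.approx(9.0)
        assert out.loc[col, "relative_risk"] == pytest.approx(3.0)

    def test_independent_feature_or_near_one(self):
        rng = np.random.default_rng(16)
        schema = default_schema()
        n = 4000
        ids = [f"l{i}" for i in range(n)]
        df = pd.DataFrame(rng.normal(size=(n, 57)), index=pd.Index(ids, name="lncrna_id"),
                          columns=schema.names)
        fun = rng.random(n) < 0.5
        records = [PredictionRecord(ids[i], 0.5, bool(fun[i])) for i in range(n)]
        out = feature_contribution(FeatureMatrix(df, schema), records)
        assert 0.8 < out["odds_ratio"].median() < 1.25

    def test_zero_cell_haldane_finite(self):
        schema = default_schema()
        ids = [f"l{i}" for i in range(4)]
        df = pd.DataFrame(np.zeros((4, 57)), index=pd.Index(ids, name="lncrna_id"),
                          columns=schema.names)
        df[schema.names[0]] = [2.0, 2.0, -2.0, -2.0]
        records = [PredictionRecord(i, 0.9, True) for i in ids]  # all Fun -> b=d=0
        out = feature_contribution(FeatureMatrix(df, schema), records)
        assert np.isfinite(out.loc[schema.names[0], "odds_ratio"])


class TestAblateAndNoise:
    def test_ablate_informative_vs_uninformative(self):
        # toy_matrix plants all signal in the first two columns = subcategory "snp"
        matrix, labeled = toy_matrix(n=60, seed=17, n_informative=2, noise=0.1)
        out = __import__("funlnc.classifier", fromlist=["ablate_categories"]).ablate_categories(
            matrix, labeled, seed=0, n_trees=100,
            subcategories=["snp", "accessibility"],
        )
        assert out.loc["snp", "delta_auroc"] < -0.1
        assert abs(out.loc["accessibility", "delta_auroc"]) < 0.1

    def test_noise_robustness_shapes_and_zero_rate(self):
        from funlnc.classifier import noise_robustness

        matrix, labeled = toy_matrix(n=60, seed=18, noise=0.1)
        out = noise_robustness(matrix, labeled, rates=(0.0, 0.3), iters=2,
                               seed=0, n_trees=50)
        assert list(out.index) == [0.0, 0.3]
        assert out.loc[0.0, "mean_auroc"] >= out.loc[0.3, "mean_auroc"] - 0.02
        assert out.loc[0.3, "sd_auroc"] >= 0.0
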