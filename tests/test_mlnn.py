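"""Feature-based predictor: reduction, MCC search, ensemble training."""

import numpy as np
import pandas as pd
import pytest

from spip.mlnn import (
    EnsembleModel,
    FeatureTable,
    combine_predictors,
    cv_mcc,
    greedy_feature_search,
    homology_reduce,
    mcc,
    score_all_mlnn,
    train_ensemble,
)


def _table(X: np.ndarray, y: np.ndarray, prefix="p"):
    ids = [f"{prefix}{i:03d}" for i in range(len(X))]
    features = pd.DataFrame(
        X, index=ids, columns=[f"f{i}" for i in range(X.shape[1])]
    )
    labels = pd.Series(y.astype(int), index=ids)
    return FeatureTable(features, labels)


@pytest.fixture
def separable_table(rng):
    """One feature separates the classes; the rest are noise."""
    n = 90
    y = (np.arange(n) < 30).astype(int)
    X = rng.standard_normal((n, 6))
    X[:, 2] += 3.0 * y
    return _table(X, y)


class TestHomologyReduce:
    def _sim(self, ids, pairs, high=0.9, rng=None):
        k = len(ids)
        base = np.full((k, k), 0.1)
        np.fill_diagonal(base, 1.0)
        sim = pd.DataFrame(base, index=ids, columns=ids)
        for a, b in pairs:
            sim.loc[a, b] = sim.loc[b, a] = high
        return sim

    def test_identity_when_nothing_similar(self, separable_table):
        ids = list(separable_table.labels.index)
        sim = self._sim(ids, [])
        out = homology_reduce(separable_table, sim, threshold=0.4)
        assert list(out.labels.index) == ids

    def test_one_of_two_duplicates_retained(self, separable_table):
        ids = list(separable_table.labels.index)
        sim = self._sim(ids, [(ids[0], ids[1])])
        out = homology_reduce(separable_table, sim, threshold=0.4)
        kept = set(out.labels.index)
        assert (ids[0] in kept) != (ids[1] in kept) or not (
            ids[0] in kept and ids[1] in kept
        )
        assert len(kept) == len(ids) - 1

    def test_retained_set_is_maximal_independent(self, rng):
        n = 20
        y = (np.arange(n) < 8).astype(int)
        table = _table(rng.standard_normal((n, 3)), y)
        ids = list(table.labels.index)
        raw = rng.random((n, n))
        raw = (raw + raw.T) / 2
        np.fill_diagonal(raw, 1.0)
        sim = pd.DataFrame(raw, index=ids, columns=ids)
        thr = 0.7
        out = homology_reduce(table, sim, threshold=thr)
        kept = list(out.labels.index)
        # independence: no retained pair above threshold
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                assert sim.loc[a, b] <= thr
        # maximality: every removed protein conflicts with a kept one
        for r in set(ids) - set(kept):
            assert any(sim.loc[r, kk] > thr for kk in kept)

    def test_deterministic(self, rng):
        n = 15
        y = (np.arange(n) < 6).astype(int)
        table = _table(rng.standard_normal((n, 3)), y)
        ids = list(table.labels.index)
        raw = rng.random((n, n))
        raw = (raw + raw.T) / 2
        sim = pd.DataFrame(raw, index=ids, columns=ids)
        a = homology_reduce(table, sim, 0.6).labels.index
        b = homology_reduce(table, sim, 0.6).labels.index
        assert list(a) == list(b)

    def test_bad_threshold_rejected(self, separable_table):
        ids = list(separable_table.labels.index)
        sim = self._sim(ids, [])
        with pytest.raises(ValueError):
            homology_reduce(separable_table, sim, threshold=1.5)


class TestMcc:
    def test_perfect_prediction(self):
        assert mcc(10, 0, 10, 0) == 1.0

    def test_fully_inverted(self):
        assert mcc(0, 10, 0, 10) == -1.0

    def test_direct_formula_value(self):
        tp, fp, tn, fn = 3, 1, 4, 2
        expected = (3 * 4 - 1 * 2) / np.sqrt((3 + 1) * (3 + 2) * (4 + 1) * (4 + 2))
        assert mcc(tp, fp, tn, fn) == pytest.approx(expected)

    def test_zero_denominator_convention(self):
        assert mcc(0, 0, 5, 5) == 0.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            mcc(0, 0, 0, 0)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import matthews_corrcoef

        for _ in range(20):
            y = rng.integers(0, 2, size=40)
            pred = rng.integers(0, 2, size=40)
            if len(np.unique(y)) < 2:
                continue
            tp = int(((pred == 1) & (y == 1)).sum())
            fp = int(((pred == 1) & (y == 0)).sum())
            tn = int(((pred == 0) & (y == 0)).sum())
            fn = int(((pred == 0) & (y == 1)).sum())
            assert mcc(tp, fp, tn, fn) == pytest.approx(
                matthews_corrcoef(y, pred), abs=1e-12
            )


class TestGreedySearch:
    def test_planted_feature_found_first(self, separable_table):
        subsets = greedy_feature_search(separable_table, seed=0)
        assert "f2" in subsets[0]
        scores = {s: cv_mcc(separable_table, s, seed=0) for s in subsets}
        assert max(scores.values()) > 0.8

    def test_pure_noise_terminates_with_low_mcc(self, rng):
        n = 60
        y = (np.arange(n) < 20).astype(int)
        table = _table(rng.standard_normal((n, 5)), y)
        subsets = greedy_feature_search(table, seed=0)
        best = max(cv_mcc(table, s, seed=0) for s in subsets)
        assert best < 0.45

    def test_jointly_informative_pair_beats_singles(self, rng):
        # XOR-style labels: neither feature alone separates, the pair does
        n = 150
        a = rng.integers(0, 2, size=n)
        b = rng.integers(0, 2, size=n)
        y = (a ^ b).astype(int)
        X = np.column_stack([
            2 * a - 1 + 0.05 * rng.standard_normal(n),
            2 * b - 1 + 0.05 * rng.standard_normal(n),
            rng.standard_normal(n),
        ])
        table = _table(X, y)
        pair = cv_mcc(table, ("f0", "f1"), seed=0)
        singles = max(cv_mcc(table, ("f0",), seed=0), cv_mcc(table, ("f1",), seed=0))
        assert pair > singles + 0.3
        subsets = greedy_feature_search(table, seed=0, n_top_singles=3)
        assert {"f0", "f1"} <= set(subsets[0])

    def test_degenerate_labels_rejected(self, rng):
        n = 20
        table = _table(rng.standard_normal((n, 3)), np.ones(n))
        with pytest.raises(ValueError, match="degenerate"):
            greedy_feature_search(table)


class TestEnsemble:
    def test_separable_fixture_high_cv_mcc(self, separable_table):
        subsets = greedy_feature_search(separable_table, seed=0)
        model = train_ensemble(separable_table, subsets, seed=0)
        assert max(model.metadata["cv_mcc"].values()) > 0.8
        assert len(model.members) == 12  # 4 subsets x 3 restarts

    def test_label_permutation_destroys_signal(self, separable_table, rng):
        permuted = FeatureTable(
            separable_table.features,
            pd.Series(
                rng.permutation(separable_table.labels.to_numpy()),
                index=separable_table.labels.index,
            ),
        )
        score = cv_mcc(permuted, ("f2",), seed=0)
        assert abs(score) < 0.35

    def test_single_member_ensemble_is_that_net(self, separable_table):
        model = train_ensemble(separable_table, [("f2",)], nets_per_subset=1, seed=0)
        assert len(model.members) == 1
        preds = model.predict(separable_table.features)
        member = model.members[0].predict(separable_table.features)
        assert np.allclose(preds.to_numpy(), member)

    def test_outputs_in_unit_interval_and_column_order_invariant(
        self, separable_table
    ):
        model = train_ensemble(separable_table, [("f2", "f0")], seed=0)
        p1 = model.predict(separable_table.features)
        shuffled = separable_table.features[
            list(reversed(separable_table.features.columns))
        ]
        p2 = model.predict(shuffled)
        assert np.allclose(p1.to_numpy(), p2.to_numpy())
        assert p1.min() >= 0.0 and p1.max() <= 1.0

    def test_deterministic_given_seed(self, separable_table):
        m1 = train_ensemble(separable_table, [("f2",)], seed=5)
        m2 = train_ensemble(separable_table, [("f2",)], seed=5)
        assert np.allclose(
            m1.predict(separable_table.features),
            m2.predict(separable_table.features),
        )

    def test_json_round_trip(self, separable_table):
        model = train_ensemble(separable_table, [("f2",)], seed=0)
        clone = EnsembleModel.from_json(model.to_json())
        assert np.allclose(
            model.predict(separable_table.features),
            clone.predict(separable_table.features),
        )

    def test_non_finite_features_rejected(self, separable_table):
        model = train_ensemble(separable_table, [("f2",)], seed=0)
        bad = separable_table.features.copy()
        bad.iloc[0, 2] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            model.predict(bad)


class TestCombine:
    def test_equal_models_combine_to_themselves(self, separable_table):
        v1 = train_ensemble(separable_table, [("f2",)], seed=0)
        combined = combine_predictors(v1, v1, separable_table)
        assert combined.report["auc_combined"] == pytest.approx(
            combined.report["auc_v1"]
        )

    def test_combination_not_much_worse_than_best(self, separable_table):
        v1 = train_ensemble(separable_table, [("f2",)], seed=0)
        v2 = train_ensemble(separable_table, [("f0", "f1")], seed=1)
        combined = combine_predictors(v1, v2, separable_table)
        best = max(combined.report["auc_v1"], combined.report["auc_v2"])
        assert combined.report["auc_combined"] >= best - 0.05

    def test_auc_two_ways_agree(self, separable_table):
        # rank-statistic AUC vs trapezoid AUC on the same scores
        from sklearn.metrics import roc_auc_score, roc_curve, auc as sk_auc
        from scipy.stats import rankdata

        v1 = train_ensemble(separable_table, [("f2",)], seed=0)
        y = separable_table.labels.to_numpy()
        s = v1.predict(separable_table.labeled_features()).to_numpy()
        fpr, tpr, _ = roc_curve(y, s)
        trapezoid = sk_auc(fpr, tpr)
        ranks = rankdata(s)
        n1 = int(y.sum())
        n0 = len(y) - n1
        mann_whitney = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
        assert trapezoid == pytest.approx(mann_whitney, abs=1e-12)
        assert roc_auc_score(y, s) == pytest.approx(mann_whitney, abs=1e-12)

    def test_disjoint_feature_space_rejected(self, separable_table, rng):
        v1 = train_ensemble(separable_table, [("f2",)], seed=0)
        other = _table(rng.standard_normal((30, 2)), (np.arange(30) < 10), prefix="q")
        other.features.columns = ["g0", "g1"]
        v2 = train_ensemble(other, [("g0",)], seed=0)
        with pytest.raises(ValueError, match="lacks features"):
            combine_predictors(v1, v2, separable_table)


def test_score_all_protocol_scores_everyone(separable_table):
    out = score_all_mlnn(
        separable_table.features, separable_table.labels, sim=None, seed=0
    )
    assert len(out) == len(separable_table.features)
    assert all(0.0 <= v <= 1.0 for v in out.scores.values())
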