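"""Feature-based spindle predictor: homology reduction, greedy
MCC-driven feature-combination search, and a cross-validated
feed-forward neural-network ensemble.

The training protocol mirrors the classic small-data neural-network
recipe: (1) reduce the labelled set so no two retained proteins are
more similar than a threshold (Hobohm-style greedy reduction), (2) rank
single features by cross-validated Matthews correlation coefficient,
grow pairs from the best singles and triplets from the best pairs until
performance stops improving, (3) train several networks per selected
feature subset and average their outputs.  Two independently trained
ensembles (e.g. successive training-set versions) combine by averaging
into a final predictor.

Networks are scikit-learn MLPClassifiers (one hidden layer of
max(2, ceil(n_features / 2)) units, lbfgs solver); after fitting, the
weights are extracted into plain arrays so that members are cheap to
serialize and evaluation does not depend on estimator internals.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .core import TargetScoreList


@dataclass
class FeatureTable:
    """Proteins x numeric features, with labels on the training subset.

    ``labels`` is indexed by a subset of ``features.index`` with values
    1 (positive) / 0 (negative); unlabeled proteins simply have no row.
    """

    features: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if not set(self.labels.index) <= set(self.features.index):
            raise ValueError("labels refer to proteins without features")
        if not np.isfinite(self.features.to_numpy(dtype=float)).all():
            raise ValueError("non-finite feature values")

    def labeled_features(self) -> pd.DataFrame:
        return self.features.loc[self.labels.index]


def homology_reduce(
    table: FeatureTable, sim: pd.DataFrame, threshold: float
) -> FeatureTable:
    """Drop labelled proteins until no retained pair is more similar
    than ``threshold``.

    Greedy reduction on the threshold graph: repeatedly remove the
    protein with the most above-threshold neighbours (ties broken by
    identifier), leaving a maximal independent set.  Unlabelled
    proteins are untouched.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    ids = sorted(table.labels.index)
    missing = [p for p in ids if p not in sim.index or p not in sim.columns]
    if missing:
        raise ValueError(f"similarity matrix misses labelled proteins {missing[:5]}")
    neigh: dict[str, set[str]] = {p: set() for p in ids}
    for i, p in enumerate(ids):
        for q in ids[i + 1 :]:
            if sim.loc[p, q] > threshold:
                neigh[p].add(q)
                neigh[q].add(p)
    removed: set[str] = set()
    while True:
        candidates = [(len(neigh[p]), p) for p in ids if p not in removed and neigh[p]]
        if not candidates:
            break
        most = max(n for n, _ in candidates)
        # ties by ID: the lexicographically smallest of the worst offenders goes
        worst = min(p for n, p in candidates if n == most)
        removed.add(worst)
        for q in neigh[worst]:
            neigh[q].discard(worst)
        neigh[worst] = set()
    kept = [p for p in ids if p not in removed]
    return FeatureTable(table.features, table.labels.loc[kept])


def mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient from a 2x2 confusion table.

    Returns 0 when any denominator factor vanishes (the conventional
    limit); an all-zero table is undefined.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("negative counts")
    if tp + fp + tn + fn == 0:
        raise ValueError("empty confusion table")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def _hidden_size(n_features: int) -> int:
    return max(2, math.ceil(n_features / 2))


def _fit_net(X: np.ndarray, y: np.ndarray, seed: int) -> MLPClassifier:
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    net = MLPClassifier(
        hidden_layer_sizes=(_hidden_size(X.shape[1]),),
        solver="lbfgs",
        max_iter=400,
        random_state=seed,
    )
    with warnings.catch_warnings():
        # lbfgs line-search abandons are routine on tiny separable folds
        warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit(X, y)
    return net


def _standardize(train: np.ndarray, *others: np.ndarray):
    mean = train.mean(axis=0)
    scale = train.std(axis=0)
    scale[scale == 0] = 1.0
    return tuple((a - mean) / scale for a in (train, *others)) + (mean, scale)


def cv_mcc(
    table: FeatureTable, subset: Sequence[str], folds: int = 3, seed: int = 0
) -> float:
    """Cross-validated test MCC of a feed-forward net on one feature subset."""
    X = table.labeled_features()[list(subset)].to_numpy(dtype=float)
    y = table.labels.to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes for cross-validation")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    tp = fp = tn = fn = 0
    for k, (tr, te) in enumerate(skf.split(X, y)):
        Xtr, Xte, _, _ = _standardize(X[tr], X[te])
        net = _fit_net(Xtr, y[tr], seed + k)
        pred = net.predict(Xte)
        tp += int(((pred == 1) & (y[te] == 1)).sum())
        fp += int(((pred == 1) & (y[te] == 0)).sum())
        tn += int(((pred == 0) & (y[te] == 0)).sum())
        fn += int(((pred == 0) & (y[te] == 1)).sum())
    return mcc(tp, fp, tn, fn)


def greedy_feature_search(
    table: FeatureTable,
    folds: int = 3,
    seed: int = 0,
    top_k: int = 4,
    n_top_singles: int = 6,
    n_top_pairs: int = 4,
) -> list[tuple[str, ...]]:
    """Stagewise feature-combination search driven by test MCC.

    Singles are ranked first; pairs are built from the best singles,
    triplets from the best pairs, and the search stops as soon as the
    best new combination fails to beat the incumbent MCC.  Returns the
    ``top_k`` best subsets seen (default 4, feeding a 12-network
    ensemble at 3 nets per subset).
    """
    y = table.labels
    if y.nunique() < 2:
        raise ValueError("degenerate labels: need positives and negatives")
    scored: dict[tuple[str, ...], float] = {}

    def evaluate(subsets: Iterable[tuple[str, ...]]) -> float:
        best = -2.0
        for sub in subsets:
            if sub not in scored:
                scored[sub] = cv_mcc(table, sub, folds=folds, seed=seed)
            best = max(best, scored[sub])
        return best

    singles = [(f,) for f in table.features.columns]
    incumbent = evaluate(singles)
    ranked_singles = sorted(singles, key=lambda s: (-scored[s], s))
    top_singles = [s[0] for s in ranked_singles[:n_top_singles]]

    pairs = [tuple(sorted(c)) for c in itertools.combinations(top_singles, 2)]
    if pairs:
        best_pair_mcc = evaluate(pairs)
        if best_pair_mcc > incumbent:
            incumbent = best_pair_mcc
            ranked_pairs = sorted(pairs, key=lambda s: (-scored[s], s))
            triplets = {
                tuple(sorted(set(p) | {f}))
                for p in ranked_pairs[:n_top_pairs]
                for f in top_singles
                if f not in p
            }
            evaluate(sorted(triplets))

    ranking = sorted(scored.items(), key=lambda kv: (-kv[1], kv[0]))
    return [sub for sub, _ in ranking[:top_k]]


@dataclass
class EnsembleMember:
    """One trained network: feature subset, scaler and weight arrays."""

    subset: tuple[str, ...]
    mean: np.ndarray
    scale: np.ndarray
    coefs: list[np.ndarray]
    intercepts: list[np.ndarray]

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        X = features[list(self.subset)].to_numpy(dtype=float)
        a = (X - self.mean) / self.scale
        last = len(self.coefs) - 1
        for i, (W, b) in enumerate(zip(self.coefs, self.intercepts)):
            a = a @ W + b
            if i < last:
                a = np.maximum(a, 0.0)  # relu hidden layers
        from scipy.special import expit

        return expit(a[:, 0])  # logistic output


@dataclass
class EnsembleModel:
    """Average of feed-forward networks over selected feature subsets."""

    members: list[EnsembleMember]
    metadata: dict = field(default_factory=dict)

    def predict(self, features: pd.DataFrame) -> pd.Series:
        if not np.isfinite(
            features[sorted({f for m in self.members for f in m.subset})]
            .to_numpy(dtype=float)
        ).all():
            raise ValueError("non-finite feature values")
        out = np.mean([m.predict(features) for m in self.members], axis=0)
        return pd.Series(out, index=features.index)

    def to_json(self) -> str:
        payload = {
            "format_version": 1,
            "metadata": self.metadata,
            "members": [
                {
                    "subset": list(m.subset),
                    "mean": m.mean.tolist(),
                    "scale": m.scale.tolist(),
                    "coefs": [w.tolist() for w in m.coefs],
                    "intercepts": [b.tolist() for b in m.intercepts],
                }
                for m in self.members
            ],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "EnsembleModel":
        payload = json.loads(text)
        members = [
            EnsembleMember(
                subset=tuple(m["subset"]),
                mean=np.asarray(m["mean"]),
                scale=np.asarray(m["scale"]),
                coefs=[np.asarray(w) for w in m["coefs"]],
                intercepts=[np.asarray(b) for b in m["intercepts"]],
            )
            for m in payload["members"]
        ]
        return cls(members=members, metadata=payload.get("metadata", {}))


def train_ensemble(
    table: FeatureTable,
    subsets: Sequence[Sequence[str]],
    nets_per_subset: int = 3,
    folds: int = 3,
    seed: int = 0,
) -> EnsembleModel:
    """Train nets_per_subset networks per feature subset (default 3 x 4 = 12).

    Each restart trains on the full labelled set with its own
    initialisation seed; per-subset cross-validated MCC is recorded as
    training metadata.  Prediction is the mean member output in [0, 1].
    """
    y = table.labels.to_numpy(dtype=int)
    members: list[EnsembleMember] = []
    cv_scores: dict[str, float] = {}
    for si, subset in enumerate(subsets):
        subset = tuple(subset)
        X = table.labeled_features()[list(subset)].to_numpy(dtype=float)
        Xs, mean, scale = _standardize(X)
        cv_scores[",".join(subset)] = cv_mcc(table, subset, folds=folds, seed=seed)
        for r in range(nets_per_subset):
            net = _fit_net(Xs, y, seed * 1000 + si * 10 + r)
            members.append(
                EnsembleMember(
                    subset=subset,
                    mean=mean,
                    scale=scale,
                    coefs=[np.asarray(w) for w in net.coefs_],
                    intercepts=[np.asarray(b) for b in net.intercepts_],
                )
            )
    return EnsembleModel(
        members=members,
        metadata={"folds": folds, "seed": seed, "cv_mcc": cv_scores,
                  "nets_per_subset": nets_per_subset},
    )


@dataclass
class CombinedPredictor:
    """Mean of two ensemble predictors trained on successive data versions."""

    v1: EnsembleModel
    v2: EnsembleModel
    report: dict = field(default_factory=dict)

    def predict(self, features: pd.DataFrame) -> pd.Series:
        return (self.v1.predict(features) + self.v2.predict(features)) / 2.0


def combine_predictors(
    v1: EnsembleModel, v2: EnsembleModel, eval_table: FeatureTable
) -> CombinedPredictor:
    """Combine two ensembles by averaging; report AUCs on an evaluation set."""
    from sklearn.metrics import roc_auc_score

    feats1 = {f for m in v1.members for f in m.subset}
    feats2 = {f for m in v2.members for f in m.subset}
    missing = (feats1 | feats2) - set(eval_table.features.columns)
    if missing:
        raise ValueError(f"evaluation table lacks features {sorted(missing)}")
    X = eval_table.labeled_features()
    y = eval_table.labels.to_numpy(dtype=int)
    p1 = v1.predict(X).to_numpy()
    p2 = v2.predict(X).to_numpy()
    combined = CombinedPredictor(v1, v2)
    combined.report = {
        "auc_v1": float(roc_auc_score(y, p1)),
        "auc_v2": float(roc_auc_score(y, p2)),
        "auc_combined": float(roc_auc_score(y, (p1 + p2) / 2.0)),
    }
    return combined


def score_all_mlnn(
    features: pd.DataFrame,
    labels: pd.Series,
    sim: pd.DataFrame | None = None,
    seed: int = 0,
    threshold: float = 0.4,
    folds: int = 3,
    top_k: int = 4,
    nets_per_subset: int = 3,
) -> TargetScoreList:
    """Full training protocol producing the MLNN evidence channel.

    Homology-reduces the labelled set (when a similarity matrix is
    given), runs the greedy feature search, trains the ensemble and
    scores every protein in the feature table.
    """
    table = FeatureTable(features, labels)
    if sim is not None:
        table = homology_reduce(table, sim, threshold)
    subsets = greedy_feature_search(table, folds=folds, seed=seed, top_k=top_k)
    model = train_ensemble(
        table, subsets, nets_per_subset=nets_per_subset, folds=folds, seed=seed
    )
    preds = model.predict(features)
    out = TargetScoreList(
        method="MLNN",
        scores={p: float(v) for p, v in preds.items()},
        metadata={"subsets": [",".join(s) for s in subsets],
                  "n_labeled": int(len(table.labels))},
    )
    return out
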