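"""Binary classifiers for synchronization prediction, and their evaluation.

Four classifier kinds:

* ``rf`` — random forest (500 trees);
* ``gb`` — gradient boosting (500 rounds, learning rate 0.1, depth 3);
* ``ffnn`` — feed-forward net (two hidden layers of 128, ReLU, Adam 1e-3,
  early stopping), with input standardization;
* ``graphlrcn`` — a recurrent network over per-iteration frames in which
  the dynamics are encoded onto the graph's adjacency matrix (see
  ``encode_lrcn_frames``); unlike the others it sees the full adjacency
  structure, and it requires r >= 1 framed iterations.

All kinds share the probability-threshold convention: predict 1 iff the
estimated probability is >= 0.5 (ties positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .data import Dataset, Sample
from .features import feature_matrix
from .nets import RecurrentFrameNet

__all__ = [
    "CLASSIFIER_KINDS",
    "ClassifierModel",
    "EvalReport",
    "train_classifier",
    "predict",
    "evaluate",
    "cross_validate",
    "encode_lrcn_frames",
    "frames_for_dataset",
    "gini_importance_experiment",
]

CLASSIFIER_KINDS = ("rf", "gb", "ffnn", "graphlrcn")

DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "rf": {"n_estimators": 500},
    "gb": {"n_estimators": 500, "learning_rate": 0.1, "max_depth": 3},
    "ffnn": {
        "hidden_layer_sizes": (128, 128),
        "learning_rate_init": 1e-3,
        "max_iter": 100,
        "early_stopping": True,
        "validation_fraction": 0.1,
    },
    "graphlrcn": {"enc_dim": 64, "hidden_dim": 64, "lr": 1e-3, "max_epochs": 30},
}


@dataclass
class ClassifierModel:
    kind: str
    estimator: object
    schema: str
    seed: int


@dataclass(frozen=True)
class EvalReport:
    """Confusion counts with derived metrics; undefined ratios are None."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def precision(self) -> float | None:
        d = self.tp + self.fp
        return None if d == 0 else self.tp / d

    @property
    def recall(self) -> float | None:
        d = self.tp + self.fn
        return None if d == 0 else self.tp / d


def _build_estimator(kind: str, hyperparams: dict | None, seed: int):
    hp = dict(DEFAULT_HYPERPARAMS[kind])
    if hyperparams:
        hp.update(hyperparams)
    if kind == "rf":
        return RandomForestClassifier(random_state=seed, **hp)
    if kind == "gb":
        return GradientBoostingClassifier(random_state=seed, **hp)
    if kind == "ffnn":
        return make_pipeline(StandardScaler(), MLPClassifier(random_state=seed, **hp))
    if kind == "graphlrcn":
        return RecurrentFrameNet(seed=seed, **hp)
    raise ValueError(f"unknown classifier kind {kind!r}; choose from {CLASSIFIER_KINDS}")


def _input_schema(kind: str, X: np.ndarray) -> str:
    if kind == "graphlrcn":
        return "frames:" + "x".join(map(str, X.shape[1:]))
    return f"flat:{X.shape[1]}"


def train_classifier(
    kind: str,
    X: np.ndarray,
    y: np.ndarray,
    hyperparams: dict | None = None,
    seed: int = 0,
    schema: str | None = None,
) -> ClassifierModel:
    """Fit one classifier; deterministic given the seed.

    ``graphlrcn`` expects frame stacks (B, T, n, n); the other kinds expect
    flat feature matrices (B, d).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    est = _build_estimator(kind, hyperparams, seed)
    if kind == "graphlrcn":
        if X.ndim not in (3, 4):
            raise ValueError("graphlrcn expects (B, T, n, n) frames")
        if X.shape[1] < 2:
            raise ValueError("graphlrcn requires r >= 1 (at least two frames)")
        est.fit(X, y)
    else:
        est.fit(X, y)
    return ClassifierModel(kind, est, schema or _input_schema(kind, X), seed)


def predict(model: ClassifierModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels and positive-class probabilities; label = 1 iff prob >= 0.5."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] == 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0)
    schema = _input_schema(model.kind, X)
    if schema != model.schema:
        raise ValueError(f"input schema {schema!r} does not match model schema {model.schema!r}")
    if model.kind == "graphlrcn":
        prob = model.estimator.predict_proba(X)
    else:
        prob = model.estimator.predict_proba(X)[:, 1]
    return (prob >= 0.5).astype(np.int64), prob


def evaluate(y_pred: np.ndarray, y_true: np.ndarray) -> EvalReport:
    y_pred = np.asarray(y_pred, dtype=np.int64)
    y_true = np.asarray(y_true, dtype=np.int64)
    if y_pred.shape != y_true.shape:
        raise ValueError("prediction/label length mismatch")
    return EvalReport(
        tp=int(((y_pred == 1) & (y_true == 1)).sum()),
        fp=int(((y_pred == 1) & (y_true == 0)).sum()),
        fn=int(((y_pred == 0) & (y_true == 1)).sum()),
        tn=int(((y_pred == 0) & (y_true == 0)).sum()),
    )


def _dataset_inputs(
    dataset: Dataset,
    kind: str,
    r_used: int,
    include_graph: bool,
    include_quartiles: bool,
    include_dynamics: bool,
) -> tuple[np.ndarray, np.ndarray]:
    if kind == "graphlrcn":
        return frames_for_dataset(dataset, r_used), dataset.labels
    X, y, _, _ = feature_matrix(
        dataset, r_used, include_graph, include_quartiles, include_dynamics
    )
    return X, y


def cross_validate(
    kind: str,
    dataset: Dataset,
    folds: int = 5,
    r_used: int | None = None,
    include_graph: bool = True,
    include_quartiles: bool = True,
    include_dynamics: bool = True,
    seed: int = 0,
    hyperparams: dict | None = None,
) -> dict:
    """Stratified k-fold cross-validation; mean and sd of the metrics."""
    r_used = dataset.spec.r if r_used is None else r_used
    X, y = _dataset_inputs(
        dataset, kind, r_used, include_graph, include_quartiles, include_dynamics
    )
    if len(y) < folds:
        raise ValueError("fewer samples than folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs, precs, recs = [], [], []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        model = train_classifier(kind, X[tr], y[tr], hyperparams, seed=seed + fold)
        pred, _ = predict(model, X[te])
        rep = evaluate(pred, y[te])
        accs.append(rep.accuracy)
        if rep.precision is not None:
            precs.append(rep.precision)
        if rep.recall is not None:
            recs.append(rep.recall)

    def agg(vals):
        if not vals:
            return {"mean": None, "sd": None}
        return {"mean": float(np.mean(vals)), "sd": float(np.std(vals))}

    return {"accuracy": agg(accs), "precision": agg(precs), "recall": agg(recs), "folds": folds}


# ---------------------------------------------------------------------------
# GraphLRCN frame encoding
# ---------------------------------------------------------------------------

def encode_lrcn_frames(
    sample: Sample,
    r_used: int,
    model: str,
    kappa: int | None = None,
    n_max: int | None = None,
) -> np.ndarray:
    """Encode rows 0..r_used of a trajectory onto the adjacency matrix.

    Frame t has off-diagonal entry (i, j) = A_ij * s(X_t(i), X_t(j)) for a
    phase-agreement kernel s in [0, 1] (continuous: (1 + cos dphi) / 2;
    discrete: 1 - circular colour distance / floor(kappa/2)), and diagonal
    entry (i, i) = X_t(i) normalized to [0, 1].  Graphs smaller than
    ``n_max`` are padded with isolated zero rows.
    """
    n = sample.graph.num_nodes
    if r_used > sample.trajectory.shape[0] - 1:
        raise ValueError("r_used exceeds stored horizon")
    n_max = n if n_max is None else n_max
    if n > n_max:
        raise ValueError(f"graph has {n} nodes > n_max={n_max}")
    A = sample.graph.adjacency(n_pad=n_max)
    frames = np.zeros((r_used + 1, n_max, n_max))
    for t in range(r_used + 1):
        x = np.asarray(sample.trajectory[t], dtype=np.float64)
        if model == "km":
            s = 0.5 * (1.0 + np.cos(x[:, None] - x[None, :]))
            diag = x / (2 * np.pi)
        else:
            d = np.abs(x[:, None] - x[None, :])
            d = np.minimum(d, kappa - d)
            s = 1.0 - d / (kappa // 2)
            diag = x / (kappa - 1)
        frame = frames[t]
        frame[:n, :n] = A[:n, :n] * s
        frame[np.arange(n), np.arange(n)] = diag
    return frames


def frames_for_dataset(dataset: Dataset, r_used: int, n_max: int | None = None) -> np.ndarray:
    if n_max is None:
        n_max = max(s.graph.num_nodes for s in dataset.samples)
    return np.stack(
        [
            encode_lrcn_frames(s, r_used, dataset.spec.model, dataset.spec.kappa, n_max)
            for s in dataset.samples
        ]
    )


# ---------------------------------------------------------------------------
# Gini importance
# ---------------------------------------------------------------------------

def gini_importance_experiment(
    dataset: Dataset,
    n_splits: int = 300,
    r_used: int = 0,
    seed: int = 0,
    test_fraction: float = 0.2,
    include_dynamics: bool = False,
    hyperparams: dict | None = None,
):
    """Distribution of gradient-boosting Gini importances over train/test splits.

    For each split a GB classifier is fitted on the graph-statistics and
    initial-quartile blocks (plus the dynamics block up to ``r_used`` when
    requested) and the normalized mean decrease in Gini impurity of every
    feature is recorded.  Returns a (n_splits x n_features) DataFrame.
    """
    import pandas as pd

    X, y, _, names = feature_matrix(
        dataset,
        r_used,
        include_graph=True,
        include_quartiles=True,
        include_dynamics=include_dynamics,
    )
    sss = StratifiedShuffleSplit(
        n_splits=n_splits, test_size=test_fraction, random_state=seed
    )
    rows = []
    for i, (tr, _te) in enumerate(sss.split(X, y)):
        model = train_classifier("gb", X[tr], y[tr], hyperparams, seed=seed + i)
        rows.append(model.estimator.feature_importances_)
    return pd.DataFrame(np.array(rows), columns=list(names))
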