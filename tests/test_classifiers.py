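"""Classifier training, prediction, evaluation, CV, frame encoding, Gini."""

import numpy as np
import pytest

from l2psync.classifiers import (
    CLASSIFIER_KINDS,
    cross_validate,
    encode_lrcn_frames,
    evaluate,
    frames_for_dataset,
    gini_importance_experiment,
    predict,
    train_classifier,
)

TINY_NET = {
    "channels": (2, 4),
    "enc_dim": 16,
    "hidden_dim": 16,
    "lr": 5e-3,
    "max_epochs": 60,
    "patience": 60,
}


def _toy_features(n=200, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 6))
    y = (X[:, 0] > 0).astype(int)
    return X, y


def _toy_frames(n=200, seed=0):
    rng = np.random.default_rng(seed)
    F = rng.normal(size=(n, 3, 8, 8))
    y = rng.integers(0, 2, n)
    F += 0.5 * y[:, None, None, None]  # class-dependent frame shift
    return F, y


@pytest.mark.parametrize("kind", ["rf", "gb", "ffnn"])
def test_separable_toy_reaches_high_train_accuracy(kind):
    X, y = _toy_features()
    hp = (
        {"n_estimators": 50}
        if kind in ("rf", "gb")
        else {"max_iter": 400, "early_stopping": False}
    )
    model = train_classifier(kind, X, y, hyperparams=hp, seed=0)
    pred, _ = predict(model, X)
    assert (pred == y).mean() >= 0.99


def test_graphlrcn_learns_separable_frames():
    F, y = _toy_frames()
    model = train_classifier("graphlrcn", F, y, hyperparams=TINY_NET, seed=0)
    pred, _ = predict(model, F)
    assert (pred == y).mean() >= 0.95


@pytest.mark.parametrize("kind", CLASSIFIER_KINDS)
def test_training_is_deterministic(kind):
    if kind == "graphlrcn":
        X, y = _toy_frames(80)
        hp = dict(TINY_NET, max_epochs=5)
    else:
        X, y = _toy_features(80)
        hp = {"n_estimators": 20} if kind in ("rf", "gb") else None
    m1 = train_classifier(kind, X, y, hyperparams=hp, seed=3)
    m2 = train_classifier(kind, X, y, hyperparams=hp, seed=3)
    _, p1 = predict(m1, X)
    _, p2 = predict(m2, X)
    assert np.allclose(p1, p2)


def test_single_class_labels_rejected():
    X, _ = _toy_features(20)
    with pytest.raises(ValueError, match="single class"):
        train_classifier("rf", X, np.ones(20, dtype=int))


def test_schema_mismatch_rejected():
    X, y = _toy_features()
    model = train_classifier("rf", X, y, hyperparams={"n_estimators": 10}, seed=0)
    with pytest.raises(ValueError, match="schema"):
        predict(model, X[:, :3])


def test_predict_threshold_and_empty_input():
    X, y = _toy_features()
    model = train_classifier("rf", X, y, hyperparams={"n_estimators": 30}, seed=0)
    labels, probs = predict(model, X)
    assert ((probs >= 0.5) == labels).all()  # ties positive by construction
    empty_labels, empty_probs = predict(model, X[:0])
    assert empty_labels.size == 0 and empty_probs.size == 0


def test_evaluate_confusion_arithmetic(rng):
    rep = evaluate([1, 1, 1, 1, 0, 0, 0, 0, 0, 0], [1, 1, 1, 0, 1, 1, 0, 0, 0, 0])
    assert (rep.tp, rep.fp, rep.fn, rep.tn) == (3, 1, 2, 4)
    assert rep.precision == pytest.approx(0.75)
    assert rep.recall == pytest.approx(0.6)
    assert rep.accuracy == pytest.approx(0.7)
    # brute-force recount on random vectors
    for _ in range(50):
        yp = rng.integers(0, 2, 30)
        yt = rng.integers(0, 2, 30)
        rep = evaluate(yp, yt)
        assert rep.tp == sum(int(a == 1 and b == 1) for a, b in zip(yp, yt))
        assert rep.accuracy == pytest.approx(np.mean(yp == yt))
        assert rep.total == 30


def test_evaluate_undefined_precision_marked():
    rep = evaluate([0, 0, 0], [1, 0, 1])
    assert rep.precision is None
    assert rep.recall == 0.0
    with pytest.raises(ValueError):
        evaluate([0, 1], [0, 1, 1])


def test_cross_validate_reproducible(fca15_small):
    a = cross_validate("rf", fca15_small, r_used=3, seed=5, hyperparams={"n_estimators": 20})
    b = cross_validate("rf", fca15_small, r_used=3, seed=5, hyperparams={"n_estimators": 20})
    assert a == b
    assert 0.0 <= a["accuracy"]["mean"] <= 1.0


def test_encode_lrcn_frames_invariants(ghm30_small):
    sample = ghm30_small.samples[0]
    frames = encode_lrcn_frames(sample, 3, "ghm", kappa=5)
    assert frames.shape == (4, 30, 30)
    A = sample.graph.adjacency()
    off = ~np.eye(30, dtype=bool)
    assert (frames[:, off & (A == 0)] == 0).all()  # non-edges stay zero
    assert frames.min() >= 0.0 and frames.max() <= 1.0
    # synchronized configuration -> every edge entry at the kernel maximum
    sync = sample.trajectory.copy()
    sync[:] = 3
    s2 = type(sample)(sample.graph, sync, sample.label, sample.features, sample.quartiles)
    f2 = encode_lrcn_frames(s2, 1, "ghm", kappa=5)
    assert np.allclose(f2[0][A == 1], 1.0)
    assert np.allclose(np.diag(f2[0]), 3 / 4)


def test_encode_lrcn_frames_permutation_equivariance(rng):
    from l2psync.data import Sample
    from l2psync.graphs import Graph, NwsParams, generate_nws_plus, graph_features

    g = generate_nws_plus(NwsParams(10, 2, 0.6, 1), rng)
    traj = rng.uniform(0, 2 * np.pi, (3, 10))
    perm = rng.permutation(10)
    g_perm = Graph.from_edges(10, [(perm[u], perm[v]) for u, v in g.edge_list()])
    traj_perm = np.empty_like(traj)
    traj_perm[:, perm] = traj
    q = np.quantile(traj[0], [0.25, 0.5, 0.75])
    s = Sample(g, traj, 1, graph_features(g), q)
    sp = Sample(g_perm, traj_perm, 1, graph_features(g_perm), q)
    f = encode_lrcn_frames(s, 2, "km")
    fp = encode_lrcn_frames(sp, 2, "km")
    assert np.allclose(fp[:, perm][:, :, perm], f)


def test_frames_padding_for_smaller_graphs(fca15_small):
    frames = frames_for_dataset(fca15_small, 2, n_max=20)
    assert frames.shape == (len(fca15_small), 3, 20, 20)
    assert (frames[:, :, 15:, :] == 0).all() and (frames[:, :, :, 15:] == 0).all()


def test_gini_importance_distribution(fca15_small):
    table = gini_importance_experiment(
        fca15_small, n_splits=8, seed=0, hyperparams={"n_estimators": 40}
    )
    assert table.shape == (8, 5 + 3)
    assert (table.values >= 0).all()
    assert np.allclose(table.sum(axis=1), 1.0)


def test_gini_noise_feature_ranks_low(rng):
    """A pure-noise column must rank below the top informative feature in
    nearly every split (spike-in control)."""
    import pandas as pd
    from sklearn.model_selection import StratifiedShuffleSplit

    n = 400
    X = rng.normal(size=(n, 4))
    y = (X[:, 0] + 0.3 * rng.normal(size=n) > 0).astype(int)
    X = np.column_stack([X, rng.uniform(size=n)])  # appended noise column
    sss = StratifiedShuffleSplit(n_splits=20, test_size=0.2, random_state=0)
    wins = 0
    for i, (tr, _) in enumerate(sss.split(X, y)):
        m = train_classifier("gb", X[tr], y[tr], {"n_estimators": 40}, seed=i)
        imp = m.estimator.feature_importances_
        wins += imp[-1] < imp[0]
    assert wins >= 19  # >= 95% of splits
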