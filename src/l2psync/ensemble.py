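"""Ensemble prediction of global synchronization from small subgraphs.

For large graphs the full dynamics may be unobserved; instead, ``k_sub``
connected induced subgraphs of ``n0`` nodes are sampled (random BFS
growth), the initial dynamics restricted to each subgraph are labelled
with the *global* outcome, and a base classifier is trained on the pooled
subgraph samples.  At prediction time the base classifier scores each of
the ``k_sub`` observed subgraphs and the mean probability is thresholded
at 0.5 (equivalent to majority vote for hard votes; even-k ties resolve
positive).  Strict majority voting is available as an alternative
aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .baseline import baseline_predict_pooled
from .classifiers import ClassifierModel, predict, train_classifier
from .data import Dataset, Sample
from .features import assemble_features
from .graphs import Graph, graph_features, sample_connected_induced_subgraph

__all__ = [
    "EnsembleSpec",
    "EnsembleModel",
    "restrict_trajectory",
    "make_subgraph_sample",
    "ensemble_train",
    "ensemble_predict",
    "sample_observations",
    "evaluate_ensemble",
]


@dataclass(frozen=True)
class EnsembleSpec:
    """n0: subgraph size; k_sub: votes per graph; base classifier settings."""

    n0: int = 30
    k_sub: int = 4
    kind: str = "ffnn"
    include_graph_features: bool = True
    include_quartiles: bool = True
    r_used: int = 1
    aggregation: str = "mean"  # "mean" probability or strict "majority"

    def __post_init__(self):
        if self.n0 < 2:
            raise ValueError("n0 must be >= 2")
        if self.k_sub < 1:
            raise ValueError("k_sub must be >= 1")
        if self.aggregation not in ("mean", "majority"):
            raise ValueError("aggregation must be 'mean' or 'majority'")


@dataclass
class EnsembleModel:
    spec: EnsembleSpec
    base: ClassifierModel


def restrict_trajectory(trajectory: np.ndarray, nodes) -> np.ndarray:
    """Select the trajectory columns of ``nodes``, in subset order."""
    trajectory = np.asarray(trajectory)
    nodes = list(nodes)
    if nodes and (min(nodes) < 0 or max(nodes) >= trajectory.shape[1]):
        raise ValueError("node index outside trajectory")
    return trajectory[:, nodes]


def make_subgraph_sample(sample: Sample, nodes, r_used: int) -> Sample:
    """Induced-subgraph view of a sample carrying the parent's global label."""
    sub_graph = sample.graph.induced_subgraph(nodes)
    sub_traj = restrict_trajectory(sample.trajectory[: r_used + 1], nodes)
    return Sample(
        graph=sub_graph,
        trajectory=sub_traj,
        label=sample.label,
        features=graph_features(sub_graph),
        quartiles=np.quantile(np.asarray(sub_traj[0], dtype=np.float64), [0.25, 0.5, 0.75]),
    )


def _feature_rows(spec: EnsembleSpec, subs: list[Sample]) -> np.ndarray:
    vecs = [
        assemble_features(
            s,
            spec.r_used,
            include_graph=spec.include_graph_features,
            include_quartiles=spec.include_quartiles,
            include_dynamics=True,
        ).values
        for s in subs
    ]
    return np.stack(vecs)


def ensemble_train(
    dataset: Dataset,
    spec: EnsembleSpec,
    rng=None,
    hyperparams: dict | None = None,
    seed: int = 0,
) -> EnsembleModel:
    """Train the base classifier on k_sub subgraph restrictions per graph."""
    rng = np.random.default_rng(rng)
    subs: list[Sample] = []
    for sample in dataset.samples:
        if sample.graph.num_nodes < spec.n0:
            raise ValueError(
                f"graph with {sample.graph.num_nodes} nodes is smaller than n0={spec.n0}"
            )
        for _ in range(spec.k_sub):
            nodes = sample_connected_induced_subgraph(sample.graph, spec.n0, rng)
            subs.append(make_subgraph_sample(sample, nodes, spec.r_used))
    X = _feature_rows(spec, subs)
    y = np.array([s.label for s in subs], dtype=np.int64)
    base = train_classifier(spec.kind, X, y, hyperparams, seed=seed)
    return EnsembleModel(spec, base)


def ensemble_predict(model: EnsembleModel, observations: list[Sample]) -> int:
    """Aggregate the base classifier's votes over k_sub observed subgraphs."""
    spec = model.spec
    for obs in observations:
        if obs.graph.num_nodes != spec.n0:
            raise ValueError("observation size differs from the trained subgraph size")
        if obs.trajectory.shape[0] < spec.r_used + 1:
            raise ValueError("observation has fewer rows than r_used + 1")
    X = _feature_rows(spec, observations)
    labels, probs = predict(model.base, X)
    if spec.aggregation == "majority":
        return int(labels.mean() >= 0.5)
    return int(probs.mean() >= 0.5)


def sample_observations(sample: Sample, spec: EnsembleSpec, rng) -> list[Sample]:
    """Draw k_sub fresh connected subgraph observations from one test graph."""
    return [
        make_subgraph_sample(
            sample,
            sample_connected_induced_subgraph(sample.graph, spec.n0, rng),
            spec.r_used,
        )
        for _ in range(spec.k_sub)
    ]


def save_observations(observations: list[Sample], path) -> None:
    """Persist one prediction's k_sub observed subgraphs: a JSON bundle
    listing, per subgraph, an edge-list file and a trajectory CSV."""
    import json
    from pathlib import Path

    from .graphs import save_edgelist

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, obs in enumerate(observations):
        gfile, tfile = f"subgraph_{i}.edgelist", f"subgraph_{i}.csv"
        save_edgelist(obs.graph, path / gfile)
        fmt = "%.17g" if np.issubdtype(np.asarray(obs.trajectory).dtype, np.floating) else "%d"
        np.savetxt(path / tfile, obs.trajectory, fmt=fmt, delimiter=",")
        entries.append({"graph": gfile, "trajectory": tfile, "label": int(obs.label)})
    with open(path / "bundle.json", "w") as fh:
        json.dump({"observations": entries}, fh, indent=1)


def load_observations(path, discrete: bool) -> list[Sample]:
    import json
    from pathlib import Path

    from .graphs import load_edgelist

    path = Path(path)
    with open(path / "bundle.json") as fh:
        bundle = json.load(fh)
    out = []
    for entry in bundle["observations"]:
        G = load_edgelist(path / entry["graph"])
        traj = np.loadtxt(
            path / entry["trajectory"],
            delimiter=",",
            dtype=np.int64 if discrete else np.float64,
            ndmin=2,
        )
        out.append(
            Sample(
                graph=G,
                trajectory=traj,
                label=int(entry["label"]),
                features=graph_features(G),
                quartiles=np.quantile(np.asarray(traj[0], dtype=np.float64), [0.25, 0.5, 0.75]),
            )
        )
    return out


def evaluate_ensemble(
    model: EnsembleModel,
    dataset: Dataset,
    rng=None,
    coin_rng=None,
) -> dict:
    """Ensemble vs pooled-concentration baseline on freshly observed subgraphs.

    For each test graph the same k_sub observations feed both the ensemble
    vote and the pooled baseline (concentration of all observed phases at
    some 1 <= t <= r, coin otherwise).  Returns predictions and labels.
    """
    rng = np.random.default_rng(rng)
    coin_rng = np.random.default_rng(coin_rng)
    spec = model.spec
    y_true, y_ens, y_base = [], [], []
    for sample in dataset.samples:
        obs = sample_observations(sample, spec, rng)
        y_true.append(sample.label)
        y_ens.append(ensemble_predict(model, obs))
        r_eff = max(1, spec.r_used)
        y_base.append(
            baseline_predict_pooled(
                [o.trajectory for o in obs],
                r_eff,
                dataset.spec.model,
                coin_rng,
                dataset.spec.kappa,
            )
        )
    return {
        "y_true": np.array(y_true),
        "y_ensemble": np.array(y_ens),
        "y_baseline": np.array(y_base),
    }
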