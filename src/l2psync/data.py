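"""Balanced, deduplicated, labelled dynamics datasets.

A *sample* is a pair (graph, initial configuration) together with the first
``r`` iterations of its trajectory and a binary label computed from the far
horizon ``T``: for KM and FCA the label is 1 iff the configuration at
iteration T is concentrated in an open half-circle; for GHM it is 1 iff the
configuration at T is synchronized (constant).

Datasets are built by rejection: graphs are drawn from the configured
source, deduplicated by Weisfeiler–Leman hash, paired with i.i.d. uniform
initial configurations, simulated to T, and kept only while the label's
per-class quota is unfilled.  Every dataset therefore has an equal number
of synchronizing and non-synchronizing examples on pairwise non-isomorphic
connected graphs.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .dynamics import (
    KmParams,
    TWO_PI,
    concentrated_continuous_batch,
    concentrated_discrete_batch,
    discrete_simulate_batch,
    km_simulate_batch,
    synchronized_discrete_batch,
)
from .graphs import (
    Graph,
    GraphFeatures,
    NwsParams,
    generate_nws_plus,
    graph_features,
    load_edgelist,
    make_topology,
    save_edgelist,
    wl_hash,
)

__all__ = [
    "TopologySpec",
    "NwsMixture",
    "DatasetSpec",
    "Sample",
    "Dataset",
    "DatasetBalanceError",
    "sample_graph",
    "label_trajectory",
    "build_balanced_dataset",
    "build_topology_contrast_dataset",
    "save_dataset",
    "load_dataset",
    "split",
]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class TopologySpec:
    """A fixed special topology as graph source (ring/path/complete/random_tree)."""

    kind: str
    n: int
    max_degree: int | None = None


@dataclass(frozen=True)
class NwsMixture:
    """NWS-plus with randomized parameters, as used for large-graph datasets.

    Per draw: n ~ Uniform{n_min..n_max}, mu ~ Uniform(mu_min, mu_max),
    p ~ Normal(mu, sigma) clipped to [0, 1], M ~ Uniform{M_min..M_max}.
    """

    n_min: int
    n_max: int
    k_nws: int = 2
    mu_min: float = 0.32
    mu_max: float = 0.62
    sigma: float = 0.04
    M_min: int = 1
    M_max: int = 20


def sample_graph(source, rng) -> Graph:
    """Draw one graph from an NwsParams, TopologySpec, or NwsMixture source."""
    if isinstance(source, NwsParams):
        return generate_nws_plus(source, rng)
    if isinstance(source, TopologySpec):
        return make_topology(source.kind, source.n, source.max_degree, rng)
    if isinstance(source, NwsMixture):
        n = int(rng.integers(source.n_min, source.n_max + 1))
        mu = rng.uniform(source.mu_min, source.mu_max)
        p = float(np.clip(rng.normal(mu, source.sigma), 0.0, 1.0))
        M = int(rng.integers(source.M_min, source.M_max + 1))
        return generate_nws_plus(NwsParams(n, source.k_nws, p, M), rng)
    raise TypeError(f"unknown graph source: {type(source).__name__}")


@dataclass(frozen=True)
class DatasetSpec:
    """Recipe for one balanced dynamics dataset.

    quota is the per-class target; r the training horizon retained in each
    sample; T the (much later) prediction iteration defining the label.
    """

    model: str  # km | fca | ghm
    graph: NwsParams | TopologySpec | NwsMixture
    r: int
    T: int
    quota: int
    kappa: int | None = 5
    km: KmParams = field(default_factory=KmParams)
    seed: int = 0
    store_full: bool = False

    def __post_init__(self):
        if self.model not in ("km", "fca", "ghm"):
            raise ValueError(f"unknown model {self.model!r}")
        if not (0 < self.r < self.T):
            raise ValueError("need T > r > 0")
        if self.quota < 1:
            raise ValueError("quota must be positive")
        if self.model != "km" and (self.kappa is None or self.kappa < 3):
            raise ValueError("discrete models need kappa >= 3")


@dataclass
class Sample:
    """One labelled example: graph, rows 0..r of its trajectory, label at T."""

    graph: Graph
    trajectory: np.ndarray  # (r+1, n)
    label: int
    features: GraphFeatures
    quartiles: np.ndarray  # (Q1, Q2, Q3) of the initial configuration
    full_trajectory: np.ndarray | None = None


@dataclass
class Dataset:
    spec: DatasetSpec
    samples: list[Sample]
    wl_hashes: list[str]

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=np.int64)

    @property
    def class_counts(self) -> tuple[int, int]:
        y = self.labels
        return int((y == 0).sum()), int((y == 1).sum())

    def __len__(self) -> int:
        return len(self.samples)


class DatasetBalanceError(RuntimeError):
    def __init__(self, msg: str, counts: tuple[int, int]):
        super().__init__(msg)
        self.counts = counts


def label_trajectory(model: str, configs: np.ndarray, T: int, kappa: int | None = None) -> int:
    """Binary label from X_T: concentration for KM/FCA, synchronization for GHM."""
    configs = np.asarray(configs)
    if configs.shape[0] < T + 1:
        raise ValueError(f"trajectory has {configs.shape[0]} rows; needs at least {T + 1}")
    row = configs[T][None, :]
    return int(_label_batch(model, row, kappa)[0])


def _label_batch(model: str, rows: np.ndarray, kappa: int | None) -> np.ndarray:
    if model == "km":
        return concentrated_continuous_batch(rows)
    if model == "fca":
        return concentrated_discrete_batch(rows, kappa)
    if model == "ghm":
        return synchronized_discrete_batch(rows)
    raise ValueError(f"unknown model {model!r}")


def _random_initial(model: str, kappa: int | None, shape, rng) -> np.ndarray:
    if model == "km":
        return rng.uniform(0.0, TWO_PI, size=shape)
    return rng.integers(0, kappa, size=shape)


def _simulate_batch(spec: DatasetSpec, A: np.ndarray, X0: np.ndarray):
    """Returns (recorded rows 0..r, X_T) for a same-size batch."""
    record = spec.T if spec.store_full else spec.r
    if spec.model == "km":
        return km_simulate_batch(A, X0, spec.T, spec.km, record_until=record)
    return discrete_simulate_batch(spec.model, A, X0, spec.kappa, spec.T, record_until=record)


def _make_sample(spec: DatasetSpec, G: Graph, rec: np.ndarray, label: int) -> Sample:
    full = rec.copy() if spec.store_full else None
    traj = rec[: spec.r + 1].copy()
    return Sample(
        graph=G,
        trajectory=traj,
        label=int(label),
        features=graph_features(G),
        quartiles=np.quantile(np.asarray(traj[0], dtype=np.float64), [0.25, 0.5, 0.75]),
        full_trajectory=full,
    )


def build_balanced_dataset(
    spec: DatasetSpec,
    rng=None,
    attempt_cap_factor: int = 50,
    batch_size: int = 512,
    progress: bool = False,
) -> Dataset:
    """Rejection-sample a balanced dataset of 2*quota examples.

    Graphs are WL-deduplicated across the whole dataset; generation stops
    when both class quotas are met or after ``attempt_cap_factor * 2 *
    quota`` attempts (then a DatasetBalanceError reports achieved counts).
    """
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    kept: dict[int, list[tuple[Sample, str]]] = {0: [], 1: []}
    seen_hashes: set[str] = set()
    attempts = 0
    cap = attempt_cap_factor * 2 * spec.quota
    while (len(kept[0]) < spec.quota or len(kept[1]) < spec.quota) and attempts < cap:
        b = min(batch_size, cap - attempts)
        attempts += b
        graphs, hashes = [], []
        for _ in range(b):
            G = sample_graph(spec.graph, rng)
            h = wl_hash(G)
            if h in seen_hashes:
                continue
            seen_hashes.add(h)
            graphs.append(G)
            hashes.append(h)
        if not graphs:
            continue
        # group by node count so each group simulates as one dense batch
        by_n: dict[int, list[int]] = {}
        for i, G in enumerate(graphs):
            by_n.setdefault(G.num_nodes, []).append(i)
        for n, idxs in sorted(by_n.items()):
            A = np.stack([graphs[i].adjacency() for i in idxs])
            X0 = _random_initial(spec.model, spec.kappa, (len(idxs), n), rng)
            rec, final = _simulate_batch(spec, A, X0)
            labels = _label_batch(spec.model, final, spec.kappa)
            for j, i in enumerate(idxs):
                lab = int(labels[j])
                if len(kept[lab]) < spec.quota:
                    kept[lab].append((_make_sample(spec, graphs[i], rec[j], lab), hashes[i]))
        if progress:
            print(f"  attempts={attempts} counts=({len(kept[0])}, {len(kept[1])})")
    if len(kept[0]) < spec.quota or len(kept[1]) < spec.quota:
        raise DatasetBalanceError(
            f"attempt cap {cap} reached with class counts "
            f"({len(kept[0])}, {len(kept[1])}) of {spec.quota} each",
            (len(kept[0]), len(kept[1])),
        )
    pairs = kept[0] + kept[1]
    order = rng.permutation(len(pairs))
    samples = [pairs[i][0] for i in order]
    hashes = [pairs[i][1] for i in order]
    return Dataset(spec, samples, hashes)


def build_topology_contrast_dataset(
    model: str,
    sync_graph: TopologySpec,
    nonsync_graph: TopologySpec,
    r: int,
    T: int,
    quota: int,
    kappa: int | None = 5,
    km: KmParams | None = None,
    seed: int = 0,
    attempt_cap_factor: int = 50,
    batch_size: int = 256,
) -> Dataset:
    """Balanced dataset whose classes live on two contrasting topologies.

    Class 1 keeps only examples on ``sync_graph`` that do synchronize by T,
    class 0 only examples on ``nonsync_graph`` that do not.  Graphs within
    a class may be isomorphic (e.g. all rings); no WL deduplication.
    """
    km = KmParams() if km is None else km
    spec = DatasetSpec(model, sync_graph, r, T, quota, kappa=kappa, km=km, seed=seed)
    rng = np.random.default_rng(seed)
    kept: dict[int, list[Sample]] = {0: [], 1: []}
    cap = attempt_cap_factor * 2 * quota
    attempts = 0
    while (len(kept[0]) < quota or len(kept[1]) < quota) and attempts < cap:
        for want, source in ((1, sync_graph), (0, nonsync_graph)):
            if len(kept[want]) >= quota:
                continue
            b = min(batch_size, quota - len(kept[want]) + 32)
            attempts += b
            graphs = [sample_graph(source, rng) for _ in range(b)]
            A = np.stack([G.adjacency() for G in graphs])
            X0 = _random_initial(model, kappa, (b, source.n), rng)
            rec, final = _simulate_batch(replace(spec, graph=source), A, X0)
            labels = _label_batch(model, final, kappa)
            for j, G in enumerate(graphs):
                if int(labels[j]) == want and len(kept[want]) < quota:
                    kept[want].append(_make_sample(spec, G, rec[j], want))
    if len(kept[0]) < quota or len(kept[1]) < quota:
        raise DatasetBalanceError(
            f"attempt cap {cap} reached with class counts ({len(kept[0])}, {len(kept[1])})",
            (len(kept[0]), len(kept[1])),
        )
    samples = kept[0] + kept[1]
    order = np.random.default_rng(seed + 1).permutation(len(samples))
    samples = [samples[i] for i in order]
    return Dataset(spec, samples, [wl_hash(s.graph) for s in samples])


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _graph_source_to_dict(src) -> dict:
    if isinstance(src, NwsParams):
        return {"type": "nws", "n": src.n, "k_nws": src.k_nws, "p": src.p, "M": src.M}
    if isinstance(src, TopologySpec):
        return {"type": "topology", "kind": src.kind, "n": src.n, "max_degree": src.max_degree}
    if isinstance(src, NwsMixture):
        return {
            "type": "nws_mixture",
            "n_min": src.n_min, "n_max": src.n_max, "k_nws": src.k_nws,
            "mu_min": src.mu_min, "mu_max": src.mu_max, "sigma": src.sigma,
            "M_min": src.M_min, "M_max": src.M_max,
        }
    raise TypeError(type(src).__name__)


def _graph_source_from_dict(d: dict):
    t = d["type"]
    if t == "nws":
        return NwsParams(d["n"], d["k_nws"], d["p"], d["M"])
    if t == "topology":
        return TopologySpec(d["kind"], d["n"], d.get("max_degree"))
    if t == "nws_mixture":
        return NwsMixture(
            d["n_min"], d["n_max"], d["k_nws"], d["mu_min"], d["mu_max"],
            d["sigma"], d["M_min"], d["M_max"],
        )
    raise ValueError(t)


def _spec_to_dict(spec: DatasetSpec) -> dict:
    return {
        "model": spec.model,
        "graph": _graph_source_to_dict(spec.graph),
        "r": spec.r,
        "T": spec.T,
        "quota": spec.quota,
        "kappa": spec.kappa,
        "km": {"K": spec.km.K, "h": spec.km.h, "omega": spec.km.omega},
        "seed": spec.seed,
        "store_full": spec.store_full,
    }


def _spec_from_dict(d: dict) -> DatasetSpec:
    return DatasetSpec(
        model=d["model"],
        graph=_graph_source_from_dict(d["graph"]),
        r=d["r"],
        T=d["T"],
        quota=d["quota"],
        kappa=d["kappa"],
        km=KmParams(**d["km"]),
        seed=d["seed"],
        store_full=d.get("store_full", False),
    )


def save_dataset(dataset: Dataset, path) -> None:
    """Write manifest.json, graphs/<id>.edgelist, dynamics/<id>.csv, labels.csv."""
    path = Path(path)
    if path.exists():
        shutil.rmtree(path)
    (path / "graphs").mkdir(parents=True)
    (path / "dynamics").mkdir()
    fmt = "%.17g" if dataset.spec.model == "km" else "%d"
    for i, s in enumerate(dataset.samples):
        save_edgelist(s.graph, path / "graphs" / f"{i}.edgelist")
        np.savetxt(path / "dynamics" / f"{i}.csv", s.trajectory, fmt=fmt, delimiter=",")
    with open(path / "labels.csv", "w") as fh:
        fh.write("sample_id,label,wl_hash\n")
        for i, (s, h) in enumerate(zip(dataset.samples, dataset.wl_hashes)):
            fh.write(f"{i},{s.label},{h}\n")
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "spec": _spec_to_dict(dataset.spec),
        "num_samples": len(dataset.samples),
        "class_counts": list(dataset.class_counts),
    }
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_dataset(path) -> Dataset:
    path = Path(path)
    with open(path / "manifest.json") as fh:
        manifest = json.load(fh)
    if manifest.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported dataset schema version {manifest.get('schema_version')}")
    spec = _spec_from_dict(manifest["spec"])
    samples, hashes = [], []
    with open(path / "labels.csv") as fh:
        header = fh.readline()
        rows = [line.strip().split(",") for line in fh if line.strip()]
    dtype = np.float64 if spec.model == "km" else np.int64
    for sid, label, h in rows:
        gpath = path / "graphs" / f"{sid}.edgelist"
        dpath = path / "dynamics" / f"{sid}.csv"
        if not gpath.exists():
            raise FileNotFoundError(f"sample {sid}: missing graph file {gpath}")
        if not dpath.exists():
            raise FileNotFoundError(f"sample {sid}: missing trajectory file {dpath}")
        G = load_edgelist(gpath)
        traj = np.loadtxt(dpath, delimiter=",", dtype=dtype, ndmin=2)
        samples.append(
            Sample(
                graph=G,
                trajectory=traj,
                label=int(label),
                features=graph_features(G),
                quartiles=np.quantile(np.asarray(traj[0], dtype=np.float64), [0.25, 0.5, 0.75]),
            )
        )
        hashes.append(h)
    return Dataset(spec, samples, hashes)


def split(dataset: Dataset, test_fraction: float = 0.2, rng=None) -> tuple[Dataset, Dataset]:
    """Stratified train/test split into two disjoint, exhaustive datasets."""
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(rng)
    y = dataset.labels
    train_idx, test_idx = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        n_test = int(round(test_fraction * len(idx)))
        if n_test < 1 or n_test >= len(idx):
            raise ValueError(f"too few samples in class {cls} for the requested split")
        idx = rng.permutation(idx)
        test_idx.extend(idx[:n_test])
        train_idx.extend(idx[n_test:])
    def take(idxs):
        idxs = sorted(int(i) for i in idxs)
        return Dataset(
            dataset.spec,
            [dataset.samples[i] for i in idxs],
            [dataset.wl_hashes[i] for i in idxs],
        )
    return take(train_idx), take(test_idx)
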