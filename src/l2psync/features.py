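"""Classifier input assembly.

A feature vector is the concatenation of up to three blocks, always in
this order:

* graph block (5): number of edges, min degree, max degree, diameter,
  number of nodes;
* quartile block (3): Q1, Q2, Q3 of the initial configuration (linear
  interpolation sample quantiles of the raw phase/colour values);
* dynamics block (n * (r_used + 1)): rows 0..r_used of the trajectory
  flattened row-major in the graph's creation node order.  r_used = 0
  means the initial configuration alone.

Phases enter as raw radians and colours as raw integers; an optional
sin/cos encoding of continuous phases is available but off by default.
Node order is never canonicalized — the classifiers are order-sensitive
and the generators' creation order is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Dataset, Sample

__all__ = ["FeatureVector", "initial_quartiles", "assemble_features", "feature_matrix"]


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    schema: str
    names: tuple

    def __len__(self) -> int:
        return len(self.values)


def initial_quartiles(x0: np.ndarray, five_number: bool = False) -> np.ndarray:
    """(Q1, Q2, Q3) of the raw values; optionally the full five-number summary."""
    x0 = np.asarray(x0, dtype=np.float64)
    qs = [0.0, 0.25, 0.5, 0.75, 1.0] if five_number else [0.25, 0.5, 0.75]
    return np.quantile(x0, qs)


def schema_tag(
    n: int,
    r_used: int,
    include_graph: bool,
    include_quartiles: bool,
    include_dynamics: bool,
    sincos: bool = False,
) -> str:
    parts = []
    if include_graph:
        parts.append("g5")
    if include_quartiles:
        parts.append("q3")
    if include_dynamics:
        d = n * (r_used + 1) * (2 if sincos else 1)
        parts.append(f"d{d}")
    return "+".join(parts) if parts else "empty"


def assemble_features(
    sample: Sample,
    r_used: int,
    include_graph: bool = True,
    include_quartiles: bool = True,
    include_dynamics: bool = True,
    sincos: bool = False,
) -> FeatureVector:
    """Assemble one sample's feature vector; see the module docstring."""
    if include_dynamics and r_used > sample.trajectory.shape[0] - 1:
        raise ValueError(
            f"r_used={r_used} exceeds stored horizon {sample.trajectory.shape[0] - 1}"
        )
    blocks, names = [], []
    if include_graph:
        blocks.append(sample.features.as_array())
        names.extend(type(sample.features).names())
    if include_quartiles:
        blocks.append(np.asarray(sample.quartiles, dtype=np.float64))
        names.extend(["q1_init", "q2_init", "q3_init"])
    if include_dynamics:
        dyn = np.asarray(sample.trajectory[: r_used + 1], dtype=np.float64)
        if sincos:
            dyn = np.concatenate([np.sin(dyn), np.cos(dyn)], axis=1)
        blocks.append(dyn.ravel())
        per_row = dyn.shape[1]
        names.extend(f"dyn_t{t}_v{v}" for t in range(r_used + 1) for v in range(per_row))
    if not blocks:
        raise ValueError("at least one feature block must be enabled")
    n = sample.graph.num_nodes
    return FeatureVector(
        np.concatenate(blocks),
        schema_tag(n, r_used, include_graph, include_quartiles, include_dynamics, sincos),
        tuple(names),
    )


def feature_matrix(
    dataset: Dataset,
    r_used: int,
    include_graph: bool = True,
    include_quartiles: bool = True,
    include_dynamics: bool = True,
    sincos: bool = False,
) -> tuple[np.ndarray, np.ndarray, str, tuple]:
    """Stack feature vectors for a whole dataset.

    Returns (X, y, schema, names).  All graphs must have the same node
    count when the dynamics block is enabled.
    """
    vecs = [
        assemble_features(s, r_used, include_graph, include_quartiles, include_dynamics, sincos)
        for s in dataset.samples
    ]
    schemas = {v.schema for v in vecs}
    if len(schemas) != 1:
        raise ValueError(f"inconsistent feature schemas across samples: {sorted(schemas)}")
    X = np.stack([v.values for v in vecs])
    return X, dataset.labels, vecs[0].schema, vecs[0].names


def export_features_csv(dataset: Dataset, path, r_used: int, **flags) -> None:
    """Write the assembled feature matrix with a named-column header and a
    trailing ``label`` column."""
    X, y, _, names = feature_matrix(dataset, r_used, **flags)
    header = ",".join([*names, "label"])
    np.savetxt(
        path,
        np.column_stack([X, y]),
        fmt="%.17g",
        delimiter=",",
        header=header,
        comments="",
    )
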