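"""The concentration-principle baseline predictor.

The classical half-circle principle guarantees synchronization of KM (with
identical intrinsic frequencies) and FCA whenever all phases fall inside
an open half-circle at any time.  The baseline predictor applies it to the
observed initial dynamics: predict synchronization if X_t is concentrated
for any 1 <= t <= r, otherwise flip a fair coin.  It never predicts
synchronization incorrectly for a concentrated KM/FCA sample, and on a
dataset with synchronizing fraction alpha in which a fraction x(r) of the
synchronizing samples concentrate by iteration r its expected accuracy is
0.5 + x(r) * alpha / 2.

For GHM "concentrated" means synchronized, so the same code serves all
three models through the model-appropriate predicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Dataset
from .dynamics import (
    concentrated_continuous_batch,
    concentrated_discrete_batch,
    synchronized_discrete_batch,
)

__all__ = [
    "BaselineStats",
    "concentrated_rows",
    "baseline_predict",
    "baseline_predict_pooled",
    "baseline_expected_accuracy",
    "concentration_fraction",
    "baseline_accuracy_empirical",
]


@dataclass(frozen=True)
class BaselineStats:
    """alpha: synchronizing fraction; x_of_r: fraction of synchronizing
    samples concentrated by iteration r."""

    alpha: float
    x_of_r: float

    def __post_init__(self):
        if not (0 <= self.alpha <= 1 and 0 <= self.x_of_r <= 1):
            raise ValueError("alpha and x_of_r must lie in [0, 1]")


def concentrated_rows(rows: np.ndarray, model: str, kappa: int | None = None) -> np.ndarray:
    """Model-appropriate concentration predicate applied to each row."""
    rows = np.atleast_2d(np.asarray(rows))
    if model == "km":
        return concentrated_continuous_batch(rows)
    if model == "fca":
        return concentrated_discrete_batch(rows, kappa)
    if model == "ghm":
        return synchronized_discrete_batch(rows)
    raise ValueError(f"unknown model {model!r}")


def _concentrates_by_r(trajectory: np.ndarray, r: int, model: str, kappa) -> bool:
    """True iff X_t is concentrated for some 1 <= t <= r (t=0 is excluded)."""
    if trajectory.shape[0] < 2:
        raise ValueError("trajectory must contain at least X_0 and X_1")
    rows = trajectory[1 : r + 1]
    return bool(concentrated_rows(rows, model, kappa).any())


def baseline_predict(trajectory: np.ndarray, r: int, model: str, rng, kappa: int | None = None) -> int:
    """Predict 1 if any X_t (1 <= t <= r) is concentrated; else a fair coin.

    ``rng`` must be a seeded numpy Generator; coins consume only this
    stream, so baseline randomness never interacts with classifier seeds.
    """
    if _concentrates_by_r(np.asarray(trajectory), r, model, kappa):
        return 1
    return int(rng.integers(0, 2))


def baseline_predict_pooled(
    trajectories: list, r: int, model: str, rng, kappa: int | None = None
) -> int:
    """Ensemble-observation variant: pool all phases observed across the
    subgraph trajectories at each t and apply the concentration test to the
    pooled multiset; coin otherwise."""
    trajs = [np.asarray(t) for t in trajectories]
    rows = np.concatenate([t[1 : r + 1] for t in trajs], axis=1)
    if concentrated_rows(rows, model, kappa).any():
        return 1
    return int(rng.integers(0, 2))


def baseline_expected_accuracy(stats: BaselineStats) -> float:
    """Closed-form expected accuracy 0.5 + x * alpha / 2."""
    return 0.5 + stats.x_of_r * stats.alpha / 2.0


def concentration_fraction(dataset: Dataset, r: int) -> BaselineStats:
    """Empirical alpha and x(r) of a labelled dataset."""
    y = dataset.labels
    alpha = float(y.mean())
    sync = [s for s in dataset.samples if s.label == 1]
    if not sync:
        return BaselineStats(alpha, 0.0)
    hits = sum(
        _concentrates_by_r(s.trajectory, r, dataset.spec.model, dataset.spec.kappa)
        for s in sync
    )
    return BaselineStats(alpha, hits / len(sync))


def baseline_accuracy_empirical(dataset: Dataset, r: int, rng) -> float:
    """Accuracy of the coin-flipping baseline on one pass over the dataset."""
    correct = 0
    for s in dataset.samples:
        pred = baseline_predict(s.trajectory, r, dataset.spec.model, rng, dataset.spec.kappa)
        correct += pred == s.label
    return correct / len(dataset)
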