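"""Coupled-oscillator dynamics: Kuramoto, Firefly CA, and Greenberg–Hastings.

Three deterministic couplings on a connected graph G:

* Kuramoto model (KM): continuous phases on the circle R/2piZ with
  identical intrinsic frequency, integrated by explicit Euler steps
  ``theta_i += h * (omega + K * sum_j sin(theta_j - theta_i))``.
* Firefly Cellular Automaton (FCA): kappa cyclic colours with blinking
  colour b = floor(kappa/2).  A node past the blink (colour > b) holds if
  some neighbour is exactly at b; every other node advances by one mod
  kappa.
* Greenberg–Hastings model (GHM): excitable medium with rest state 0,
  excited state 1, refractory states 2..kappa-1.  A resting node becomes
  excited iff a neighbour is excited; non-rest states advance mod kappa.

A configuration is *concentrated* if all phases fit in an open half-circle
(arc < pi, or a cyclic window of fewer than kappa/2 consecutive colours);
for KM (identical frequencies) and FCA, concentration at any time
guarantees eventual synchronization, the classical half-circle principle.
GHM admits no such principle, so for GHM "concentrated" means synchronized
(constant).

Batched variants operate on stacks of systems (one adjacency matrix per
system) and are the fast path used by dataset construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graphs import Graph

__all__ = [
    "ContinuousConfig",
    "DiscreteConfig",
    "KmParams",
    "Trajectory",
    "km_simulate",
    "fca_step",
    "ghm_step",
    "simulate_discrete",
    "is_concentrated_continuous",
    "is_concentrated_discrete",
    "is_synchronized",
    "is_concentrated",
    "km_simulate_batch",
    "discrete_simulate_batch",
    "concentrated_continuous_batch",
    "concentrated_discrete_batch",
    "synchronized_discrete_batch",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class ContinuousConfig:
    """Phase configuration on the circle; values reduced mod 2pi."""

    phases: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "phases", np.mod(np.asarray(self.phases, dtype=np.float64), TWO_PI))


@dataclass(frozen=True)
class DiscreteConfig:
    """Colour configuration on the kappa-colour wheel Z/kappaZ."""

    colors: np.ndarray
    kappa: int

    def __post_init__(self):
        colors = np.asarray(self.colors, dtype=np.int64)
        if self.kappa < 3:
            raise ValueError("kappa must be >= 3")
        if colors.min(initial=0) < 0 or colors.max(initial=0) >= self.kappa:
            raise ValueError("colors must lie in {0..kappa-1}")
        object.__setattr__(self, "colors", colors)


@dataclass(frozen=True)
class KmParams:
    """Kuramoto integration parameters: coupling K, Euler step h, frequency omega."""

    K: float = 1.0
    h: float = 0.1
    omega: float = 0.0

    def __post_init__(self):
        if self.K <= 0 or self.h <= 0:
            raise ValueError("K and h must be positive")

    def check_stability(self, max_degree: int) -> None:
        """Per-step phase increment must stay below pi for the largest degree."""
        bound = self.h * (abs(self.omega) + self.K * max_degree)
        if bound >= np.pi:
            raise ValueError(
                f"unstable discretization: h*(|omega| + K*max_degree) = {bound:.3f} >= pi"
            )


@dataclass(frozen=True)
class Trajectory:
    """(steps+1) x n matrix of configurations; row t is X_t."""

    configs: np.ndarray
    model: str  # "km", "fca", or "ghm"
    kappa: int | None = None

    def __post_init__(self):
        if self.model not in ("km", "fca", "ghm"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.model != "km" and self.kappa is None:
            raise ValueError("discrete trajectory requires kappa")

    @property
    def num_steps(self) -> int:
        return self.configs.shape[0] - 1

    @property
    def num_nodes(self) -> int:
        return self.configs.shape[1]

    def config_at(self, t: int):
        row = self.configs[t]
        if self.model == "km":
            return ContinuousConfig(row)
        return DiscreteConfig(row, self.kappa)


# ---------------------------------------------------------------------------
# single-system simulators (reference implementations)
# ---------------------------------------------------------------------------

def km_simulate(G: Graph, X0: ContinuousConfig, steps: int, params: KmParams = KmParams()) -> Trajectory:
    """Explicit-Euler Kuramoto trajectory for ``steps`` iterations."""
    if len(X0.phases) != G.num_nodes:
        raise ValueError("initial configuration length != number of nodes")
    params.check_stability(int(G.degrees().max(initial=0)))
    A = G.adjacency()
    out = np.empty((steps + 1, G.num_nodes))
    theta = X0.phases.copy()
    out[0] = theta
    for t in range(steps):
        diff = theta[None, :] - theta[:, None]  # diff[i, j] = theta_j - theta_i
        theta = np.mod(theta + params.h * (params.omega + params.K * (A * np.sin(diff)).sum(axis=1)), TWO_PI)
        out[t + 1] = theta
    return Trajectory(out, "km")


def fca_step(G: Graph, X: DiscreteConfig) -> DiscreteConfig:
    """One FCA update: advance mod kappa unless inhibited by a blinking neighbour."""
    b = X.kappa // 2
    A = G.adjacency(dtype=bool)
    neighbor_blinks = A @ (X.colors == b)
    hold = (X.colors > b) & neighbor_blinks
    return DiscreteConfig(np.where(hold, X.colors, (X.colors + 1) % X.kappa), X.kappa)


def ghm_step(G: Graph, X: DiscreteConfig) -> DiscreteConfig:
    """One GHM update: rest excites by contact; non-rest advances mod kappa."""
    A = G.adjacency(dtype=bool)
    excited_neighbor = A @ (X.colors == 1)
    new = np.where(X.colors == 0, np.where(excited_neighbor, 1, 0), (X.colors + 1) % X.kappa)
    return DiscreteConfig(new, X.kappa)


def simulate_discrete(model: str, G: Graph, X0: DiscreteConfig, steps: int) -> Trajectory:
    """Iterate fca_step/ghm_step; all ``steps`` rows are materialized."""
    step = {"fca": fca_step, "ghm": ghm_step}.get(model)
    if step is None:
        raise ValueError(f"unknown discrete model {model!r}")
    if len(X0.colors) != G.num_nodes:
        raise ValueError("initial configuration length != number of nodes")
    out = np.empty((steps + 1, G.num_nodes), dtype=np.int64)
    X = X0
    out[0] = X.colors
    for t in range(steps):
        X = step(G, X)
        out[t + 1] = X.colors
    return Trajectory(out, model, kappa=X0.kappa)


# ---------------------------------------------------------------------------
# concentration / synchronization predicates
# ---------------------------------------------------------------------------

def is_concentrated_continuous(X: ContinuousConfig) -> bool:
    """True iff all phases fit in an open arc of length < pi."""
    return bool(concentrated_continuous_batch(X.phases[None, :])[0])


def is_concentrated_discrete(X: DiscreteConfig) -> bool:
    """True iff occupied colours fit in a cyclic window of w < kappa/2 consecutive integers."""
    return bool(concentrated_discrete_batch(X.colors[None, :], X.kappa)[0])


def is_synchronized(X, tol: float = 1e-6) -> bool:
    """Constant configuration: exact for colours, circular tolerance for phases."""
    if isinstance(X, DiscreteConfig):
        return bool((X.colors == X.colors.flat[0]).all())
    phases = X.phases
    z = np.exp(1j * phases)
    mean_angle = np.angle(z.mean())
    dev = np.angle(np.exp(1j * (phases - mean_angle)))
    return bool(np.abs(dev).max(initial=0.0) <= tol)


def is_concentrated(X) -> bool:
    """Model-appropriate concentration predicate (GHM uses is_synchronized)."""
    if isinstance(X, ContinuousConfig):
        return is_concentrated_continuous(X)
    return is_concentrated_discrete(X)


# ---------------------------------------------------------------------------
# batched fast paths
# ---------------------------------------------------------------------------

def km_simulate_batch(
    A: np.ndarray,
    theta0: np.ndarray,
    steps: int,
    params: KmParams = KmParams(),
    record_until: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate B Kuramoto systems in lockstep.

    A: (B, n, n) adjacency stack; theta0: (B, n).  Returns ``(recorded,
    final)`` where ``recorded`` holds rows 0..record_until (default: all
    steps) for every system and ``final`` is X_steps.
    """
    A = np.asarray(A, dtype=np.float64)
    theta = np.mod(np.asarray(theta0, dtype=np.float64), TWO_PI)
    B, n = theta.shape
    r = steps if record_until is None else record_until
    if r > steps:
        raise ValueError("record_until exceeds steps")
    params.check_stability(int(A.sum(axis=2).max(initial=0)))
    rec = np.empty((B, r + 1, n))
    rec[:, 0] = theta
    h, K, omega = params.h, params.K, params.omega

    def step(A_, th):
        # sum_j A_ij sin(th_j - th_i) = cos th_i (A sin th)_i - sin th_i (A cos th)_i
        s, c = np.sin(th), np.cos(th)
        Ss = (A_ @ s[..., None])[..., 0]
        Sc = (A_ @ c[..., None])[..., 0]
        return np.mod(th + h * (omega + K * (c * Ss - s * Sc)), TWO_PI)

    final = theta.copy()
    active = np.arange(B)
    A_act, th_act = A, theta
    for t in range(1, steps + 1):
        th_act = step(A_act, th_act)
        if t <= r:
            rec[active, t] = th_act
        final[active] = th_act
        # Past the recorded horizon, systems synchronized to machine
        # precision are frozen: a constant configuration is a fixed point
        # of the rotating-frame update, so X_T equals the frozen state.
        if omega == 0 and t > r and t % 64 == 0 and len(active) > 1:
            z = np.exp(1j * th_act)
            mean = z.mean(axis=1, keepdims=True)
            dev = np.abs(np.angle(z * np.conj(mean / np.abs(mean))))
            live = dev.max(axis=1) > 1e-9
            if not live.all():
                active = active[live]
                A_act = A_act[live]
                th_act = th_act[live]
                if len(active) == 0:
                    break
    return rec, final


def discrete_simulate_batch(
    model: str,
    A: np.ndarray,
    colors0: np.ndarray,
    kappa: int,
    steps: int,
    record_until: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate B discrete systems (FCA or GHM) in lockstep; see km_simulate_batch."""
    if model not in ("fca", "ghm"):
        raise ValueError(f"unknown discrete model {model!r}")
    A = np.asarray(A, dtype=np.float64)
    colors = np.asarray(colors0, dtype=np.int64).copy()
    B, n = colors.shape
    r = steps if record_until is None else record_until
    if r > steps:
        raise ValueError("record_until exceeds steps")
    rec = np.empty((B, r + 1, n), dtype=np.int64)
    rec[:, 0] = colors
    b = kappa // 2
    for t in range(1, steps + 1):
        if model == "fca":
            blink = (A @ (colors == b)[..., None].astype(np.float64))[..., 0] > 0
            hold = (colors > b) & blink
            colors = np.where(hold, colors, (colors + 1) % kappa)
        else:
            excited = (A @ (colors == 1)[..., None].astype(np.float64))[..., 0] > 0
            colors = np.where(colors == 0, np.where(excited, 1, 0), (colors + 1) % kappa)
        if t <= r:
            rec[:, t] = colors
    return rec, colors


def concentrated_continuous_batch(phases: np.ndarray) -> np.ndarray:
    """Half-circle test for a (B, n) stack: largest circular gap > pi."""
    phases = np.mod(np.asarray(phases, dtype=np.float64), TWO_PI)
    if phases.shape[1] == 1:
        return np.ones(phases.shape[0], dtype=bool)
    s = np.sort(phases, axis=1)
    gaps = np.diff(s, axis=1)
    wrap = (s[:, 0] + TWO_PI - s[:, -1])[:, None]
    return np.concatenate([gaps, wrap], axis=1).max(axis=1) > np.pi


def concentrated_discrete_batch(colors: np.ndarray, kappa: int) -> np.ndarray:
    """Cyclic-window test for a (B, n) stack of colour rows.

    Concentrated iff all occupied colours fit in some window of w
    consecutive integers mod kappa with w < kappa/2 (the largest such w is
    ceil(kappa/2) - 1).
    """
    colors = np.asarray(colors, dtype=np.int64)
    B = colors.shape[0]
    occupied = np.zeros((B, kappa), dtype=bool)
    occupied[np.repeat(np.arange(B), colors.shape[1]), colors.ravel()] = True
    w = (kappa + 1) // 2 - 1  # largest integer < kappa/2
    ok = np.zeros(B, dtype=bool)
    idx = np.arange(kappa)
    for start in range(kappa):
        window = ((idx - start) % kappa) < w
        ok |= ~(occupied & ~window[None, :]).any(axis=1)
    return ok


def synchronized_discrete_batch(colors: np.ndarray) -> np.ndarray:
    colors = np.asarray(colors)
    return (colors == colors[:, :1]).all(axis=1)


def save_trajectory(traj: Trajectory, path, params: KmParams | None = None, seed=None) -> None:
    """CSV matrix (rows = time) plus a JSON sidecar with the metadata."""
    import json
    from pathlib import Path

    path = Path(path)
    fmt = "%.17g" if traj.model == "km" else "%d"
    np.savetxt(path, traj.configs, fmt=fmt, delimiter=",")
    meta = {"model": traj.model, "kappa": traj.kappa, "seed": seed}
    if params is not None:
        meta["params"] = {"K": params.K, "h": params.h, "omega": params.omega}
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(meta, fh)


def load_trajectory(path) -> Trajectory:
    import json
    from pathlib import Path

    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        meta = json.load(fh)
    dtype = np.float64 if meta["model"] == "km" else np.int64
    configs = np.loadtxt(path, delimiter=",", dtype=dtype, ndmin=2)
    return Trajectory(configs, meta["model"], kappa=meta.get("kappa"))
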