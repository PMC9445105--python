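"""Oscillator updates, concentration predicates, and batch/single agreement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from l2psync.dynamics import (
    ContinuousConfig,
    DiscreteConfig,
    KmParams,
    concentrated_continuous_batch,
    discrete_simulate_batch,
    fca_step,
    ghm_step,
    is_concentrated_continuous,
    is_concentrated_discrete,
    is_synchronized,
    km_simulate,
    km_simulate_batch,
    simulate_discrete,
)
from l2psync.graphs import Graph, generate_nws_plus, make_topology, NwsParams

EDGE = Graph.from_edges(2, [(0, 1)])


def test_km_two_node_closed_form():
    # one Euler step: theta_i += h*K*sin(theta_j - theta_i)
    traj = km_simulate(EDGE, ContinuousConfig([0.0, np.pi / 2]), 1, KmParams(1.0, 0.1, 0.0))
    assert traj.configs[1] == pytest.approx([0.1, np.pi / 2 - 0.1])


def test_km_constant_config_is_fixed_point():
    g = make_topology("ring", 6)
    traj = km_simulate(g, ContinuousConfig([1.3] * 6), 50)
    assert np.allclose(traj.configs, 1.3)


def test_km_stability_precondition():
    g = make_topology("complete", 50)
    with pytest.raises(ValueError, match="unstable"):
        km_simulate(g, ContinuousConfig(np.zeros(50)), 1, KmParams(K=1.0, h=0.1))


@pytest.mark.parametrize(
    "colors,expected",
    [([3, 2], [3, 3]), ([1, 2], [2, 3]), ([4, 1], [0, 2]), ([2, 2], [3, 3])],
)
def test_fca_step_rule(colors, expected):
    # blinking colour b(5)=2: colours > 2 hold next to a blinker, others advance
    assert fca_step(EDGE, DiscreteConfig(colors, 5)).colors.tolist() == expected


@pytest.mark.parametrize(
    "colors,expected",
    [([0, 1], [1, 2]), ([0, 0], [0, 0]), ([3, 4], [4, 0]), ([0, 3], [0, 4])],
)
def test_ghm_step_rule(colors, expected):
    assert ghm_step(EDGE, DiscreteConfig(colors, 5)).colors.tolist() == expected


def test_ghm_all_zero_absorbing(rng):
    g = generate_nws_plus(NwsParams(10, 2, 0.5, 1), rng)
    traj = simulate_discrete("ghm", g, DiscreteConfig(np.zeros(10, dtype=int), 5), 20)
    assert (traj.configs == 0).all()


def test_fca_constant_config_rotates_uniformly():
    g = make_topology("ring", 8)
    traj = simulate_discrete("fca", g, DiscreteConfig([3] * 8, 5), 10)
    for t in range(11):
        row = traj.configs[t]
        assert (row == row[0]).all()
        assert row[0] == (3 + t) % 5


def test_discrete_batch_matches_single(rng):
    for model in ("fca", "ghm"):
        graphs = [generate_nws_plus(NwsParams(12, 2, 0.6, 1), rng) for _ in range(8)]
        X0 = rng.integers(0, 5, (8, 12))
        A = np.stack([g.adjacency() for g in graphs])
        rec, final = discrete_simulate_batch(model, A, X0, 5, 30)
        for i, g in enumerate(graphs):
            traj = simulate_discrete(model, g, DiscreteConfig(X0[i], 5), 30)
            assert (rec[i] == traj.configs).all()
            assert (final[i] == traj.configs[-1]).all()


def test_km_batch_matches_single(rng):
    graphs = [generate_nws_plus(NwsParams(10, 2, 0.7, 1), rng) for _ in range(6)]
    X0 = rng.uniform(0, 2 * np.pi, (6, 10))
    A = np.stack([g.adjacency() for g in graphs])
    rec, final = km_simulate_batch(A, X0, 60)
    for i, g in enumerate(graphs):
        traj = km_simulate(g, ContinuousConfig(X0[i]), 60)
        assert np.allclose(rec[i], traj.configs, atol=1e-12)
        assert np.allclose(final[i], traj.configs[-1], atol=1e-12)


def test_trajectories_deterministic(rng):
    g = generate_nws_plus(NwsParams(12, 2, 0.6, 1), rng)
    X0 = DiscreteConfig(rng.integers(0, 5, 12), 5)
    a = simulate_discrete("fca", g, X0, 40).configs
    b = simulate_discrete("fca", g, X0, 40).configs
    assert (a == b).all()


def _min_covering_arc(phases: np.ndarray) -> float:
    """Brute-force O(n^2) oracle: length of the smallest arc containing all phases."""
    best = 2 * np.pi
    for start in phases:
        width = max((p - start) % (2 * np.pi) for p in phases)
        best = min(best, width)
    return best


def test_concentration_continuous_matches_bruteforce(rng):
    for _ in range(1000):
        n = int(rng.integers(1, 11))
        phases = rng.uniform(0, 2 * np.pi, n)
        expected = _min_covering_arc(phases) < np.pi
        assert is_concentrated_continuous(ContinuousConfig(phases)) == expected


@pytest.mark.parametrize(
    "phases,expected",
    [([0.0, 2.0, 4.0], False), ([0.0, np.pi], False), ([1.0, 1.0, 1.0], True), ([0.1, 6.2], True)],
)
def test_concentration_continuous_examples(phases, expected):
    assert is_concentrated_continuous(ContinuousConfig(phases)) is expected


def _discrete_concentrated_oracle(colors, kappa):
    """Enumerate every cyclic window of w < kappa/2 consecutive colours."""
    occupied = set(int(c) for c in colors)
    w = (kappa + 1) // 2 - 1
    for start in range(kappa):
        window = {(start + i) % kappa for i in range(w)}
        if occupied <= window:
            return True
    return False


@given(
    kappa=st.integers(3, 8),
    data=st.data(),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_concentration_discrete_matches_window_oracle(kappa, data):
    n = data.draw(st.integers(1, 8))
    colors = data.draw(st.lists(st.integers(0, kappa - 1), min_size=n, max_size=n))
    got = is_concentrated_discrete(DiscreteConfig(colors, kappa))
    assert got == _discrete_concentrated_oracle(colors, kappa)


@pytest.mark.parametrize(
    "colors,expected",
    [([1, 2], True), ([4, 0], True), ([0, 1, 2], False), ([3, 3], True)],
)
def test_concentration_discrete_examples(colors, expected):
    assert is_concentrated_discrete(DiscreteConfig(colors, 5)) is expected


def test_is_synchronized():
    assert is_synchronized(DiscreteConfig([2, 2, 2], 5))
    assert not is_synchronized(DiscreteConfig([1, 1, 2], 5))
    assert is_synchronized(ContinuousConfig([1.0, 1.0, 1.0]))
    assert is_synchronized(ContinuousConfig([1.0, 1.0 + 5e-7]))
    assert not is_synchronized(ContinuousConfig([1.0, 1.1]))


def test_steps_equivariant_under_isomorphism(rng):
    """Relabelling nodes commutes with the FCA and GHM updates."""
    g = generate_nws_plus(NwsParams(12, 2, 0.6, 1), rng)
    perm = rng.permutation(12)
    g_perm = Graph.from_edges(12, [(perm[u], perm[v]) for u, v in g.edge_list()])
    colors = rng.integers(0, 5, 12)
    colors_perm = np.empty(12, dtype=int)
    colors_perm[perm] = colors
    for step in (fca_step, ghm_step):
        out = step(g, DiscreteConfig(colors, 5)).colors
        out_perm = step(g_perm, DiscreteConfig(colors_perm, 5)).colors
        assert (out_perm[perm] == out).all()


def test_trajectory_csv_round_trip(tmp_path, rng):
    g = generate_nws_plus(NwsParams(8, 2, 0.5, 1), rng)
    traj = simulate_discrete("fca", g, DiscreteConfig(rng.integers(0, 5, 8), 5), 12)
    from l2psync.dynamics import load_trajectory, save_trajectory

    save_trajectory(traj, tmp_path / "t.csv", seed=3)
    back = load_trajectory(tmp_path / "t.csv")
    assert back.model == "fca" and back.kappa == 5
    assert (back.configs == traj.configs).all()

    km = km_simulate(g, ContinuousConfig(rng.uniform(0, 2 * np.pi, 8)), 10)
    save_trajectory(km, tmp_path / "k.csv", params=KmParams())
    back = load_trajectory(tmp_path / "k.csv")
    assert np.array_equal(back.configs, km.configs)
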