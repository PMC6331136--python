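"""Insulated heat diffusion, module extraction, significance, consensus."""

import networkx as nx
import numpy as np
import pytest

from m6aflow.diffusion import (
    SubnetworkSet, consensus, delta_min, diffusion, diffusion_series,
    exchanged_heat, extract_subnetworks, heat_vector, random_network,
    scc_sizes, select_beta, select_delta, significance_test, walk_matrix,
)


def _two_node():
    g = nx.Graph([(0, 1)])
    return walk_matrix(g, [0, 1])


def test_walk_matrix_examples():
    assert np.array_equal(_two_node(), [[0, 1], [1, 0]])
    tri = walk_matrix(nx.cycle_graph(3), [0, 1, 2])
    assert np.allclose(tri, 0.5 * (np.ones((3, 3)) - np.eye(3)))
    star = nx.star_graph(3)  # hub 0, leaves 1-3
    w = walk_matrix(star, [0, 1, 2, 3])
    assert np.allclose(w[1:, 0], 1 / 3)  # hub column splits three ways
    assert np.allclose(w[0, 1:], 1.0)  # each leaf sends all to the hub
    with pytest.raises(ValueError, match="isolated"):
        g = nx.Graph([(0, 1)])
        g.add_node(2)
        walk_matrix(g, [0, 1, 2])


def test_diffusion_two_node_hand_inversion():
    f = diffusion(_two_node(), 0.5)
    assert np.allclose(f, [[2 / 3, 1 / 3], [1 / 3, 2 / 3]], atol=1e-12)


def test_diffusion_limits_and_validation():
    w = _two_node()
    assert np.allclose(diffusion(w, 0.999999), np.eye(2), atol=1e-5)
    for beta in (0.0, 1.0, -0.2, 2.0):
        with pytest.raises(ValueError):
            diffusion(w, beta)


@pytest.mark.parametrize("seed", range(5))
def test_diffusion_matches_series_oracle(seed):
    """Closed-form inverse equals the truncated geometric series."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 80))
    g = nx.gnp_random_graph(n, 0.15, seed=seed)
    g.remove_nodes_from(list(nx.isolates(g)))
    nodes = sorted(g.nodes())
    w = walk_matrix(g, nodes)
    beta = float(rng.uniform(0.2, 0.8))
    f = diffusion(w, beta)
    assert np.abs(f - diffusion_series(w, beta, 200)).max() < 1e-8
    assert np.abs(f.sum(axis=0) - 1.0).max() < 1e-10
    assert f.min() >= 0


def test_exchanged_heat_worked_example_and_linearity():
    f = diffusion(_two_node(), 0.5)
    e = exchanged_heat(f, np.array([1.0, 0.0]))
    assert np.allclose(e, [[2 / 3, 0], [1 / 3, 0]], atol=1e-12)
    assert exchanged_heat(f, np.zeros(2)).sum() == 0
    h = np.array([0.3, 1.7])
    assert np.allclose(exchanged_heat(f, 3 * h), 3 * exchanged_heat(f, h))


@pytest.mark.parametrize("seed", range(3))
def test_heat_conservation(seed):
    """Column sums of E reproduce the heat vector to machine precision."""
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(40, 0.2, seed=seed + 100)
    g.remove_nodes_from(list(nx.isolates(g)))
    nodes = sorted(g.nodes())
    h = rng.exponential(size=len(nodes))
    f = diffusion(walk_matrix(g, nodes), 0.45)
    e = exchanged_heat(f, h)
    assert np.abs(e.sum(axis=0) - h).max() < 1e-10


def test_extract_subnetworks_cases():
    f = diffusion(_two_node(), 0.5)
    e = exchanged_heat(f, np.array([1.0, 1.0]))
    # cross terms are both 1/3 >= 0.3 -> one mutual 2-cycle
    sub = extract_subnetworks(e, 0.3, ["a", "b"])
    assert sub.sizes == [2]
    assert sub.components[0] == {"a", "b"}
    # delta above every entry -> nothing
    assert extract_subnetworks(e, 10.0, ["a", "b"]).components == []
    # asymmetric heat: one cross term above delta, the other below -> no SCC
    e2 = exchanged_heat(f, np.array([1.0, 0.5]))
    assert extract_subnetworks(e2, 0.2, ["a", "b"]).components == []
    with pytest.raises(ValueError):
        extract_subnetworks(e, 0.0, ["a", "b"])


def test_component_sizes_monotone_in_delta():
    rng = np.random.default_rng(1)
    g = nx.gnp_random_graph(30, 0.2, seed=2)
    g.remove_nodes_from(list(nx.isolates(g)))
    nodes = sorted(g.nodes())
    h = rng.exponential(size=len(nodes))
    e = exchanged_heat(diffusion(walk_matrix(g, nodes), 0.5), h)
    deltas = np.quantile(e[e > 0], [0.5, 0.7, 0.9, 0.99])
    maxima = [max(scc_sizes(e, d), default=0) for d in deltas]
    assert maxima == sorted(maxima, reverse=True)


def test_delta_min_matches_exhaustive_search():
    rng = np.random.default_rng(3)
    g = nx.gnp_random_graph(25, 0.25, seed=4)
    g.remove_nodes_from(list(nx.isolates(g)))
    nodes = sorted(g.nodes())
    h = rng.exponential(size=len(nodes))
    e = exchanged_heat(diffusion(walk_matrix(g, nodes), 0.5), h)
    values = np.unique(e[~np.eye(len(nodes), dtype=bool) & (e > 0)])
    for l_max in (2, 3, 5, 10, len(nodes)):
        brute = next(
            (v for v in values if max(scc_sizes(e, v), default=0) <= l_max),
            None,
        )
        if brute is not None:
            assert delta_min(e, l_max) == pytest.approx(float(brute))
    # L_max >= network size: constraint never binds, smallest entry returned
    assert delta_min(e, len(nodes)) == pytest.approx(float(values[0]))


def test_select_beta_contracts():
    g = nx.gnp_random_graph(40, 0.12, seed=9)
    g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
    assert select_beta(g, beta_grid=[0.35]) == 0.35  # singleton grid
    beta = select_beta(g)
    assert 0.05 <= beta <= 0.95
    with pytest.warns(UserWarning):
        assert select_beta(nx.complete_graph(6)) == 0.5  # degenerate topology


def test_path_graph_heat_locality():
    """Direct neighbors of the source retain more heat than level two."""
    g = nx.path_graph(9)
    nodes = list(g.nodes())
    f = diffusion(walk_matrix(g, nodes), 0.5)
    source = 4
    level1 = min(f[3, source], f[5, source])
    level2 = max(f[2, source], f[6, source])
    assert level1 > level2


def test_random_network_preserves_degrees():
    g = nx.gnp_random_graph(30, 0.2, seed=11)
    g.remove_nodes_from(list(nx.isolates(g)))
    r = random_network(g, seed=0)
    assert dict(g.degree()) == dict(r.degree())
    assert not any(u == v for u, v in r.edges())
    # triangles admit no double edge swap
    tri = nx.cycle_graph(3)
    assert set(random_network(tri, seed=1).edges()) == set(tri.edges())
    # seeded determinism
    a = random_network(g, seed=7)
    b = random_network(g, seed=7)
    assert set(a.edges()) == set(b.edges())


def test_significance_exchangeable_heat_is_not_significant():
    """Identical heat on every gene: permutation leaves E invariant."""
    g = nx.gnp_random_graph(25, 0.25, seed=12)
    g.remove_nodes_from(list(nx.isolates(g)))
    heat = {n: 1.0 for n in g.nodes()}
    sig = significance_test(g, heat, beta=0.5, delta=1e-4, n_perm=20, seed=0)
    assert all(p == 1.0 for p in sig.p_values.values())
    with pytest.raises(ValueError):
        significance_test(g, heat, 0.5, 1e-4, n_perm=0)


def test_select_delta_deterministic_and_bounded(network_fixture):
    g = network_fixture.networks[0]
    kwargs = dict(l_max_list=(5, 10), n_random=3, n_perm=30, seed=9)
    a = select_delta(g, network_fixture.heat, 0.5, **kwargs)
    b = select_delta(g, network_fixture.heat, 0.5, **kwargs)
    assert a.delta == b.delta
    assert a.candidates == b.candidates
    assert a.delta in a.candidates.values()
    # tighter L_max demands a larger threshold
    assert a.candidates[5] >= a.candidates[10]


def _toy_edge(u, v):
    return (u, v) if u <= v else (v, u)


def test_consensus_weights_and_functional_filter():
    # core triangle a-b-c in all four networks; edge c-d in three; d-e in
    # two; e-f in exactly one
    core = {_toy_edge("a", "b"), _toy_edge("b", "c"), _toy_edge("a", "c")}
    nets = [
        core | {_toy_edge("c", "d"), _toy_edge("d", "e"), _toy_edge("e", "f")},
        core | {_toy_edge("c", "d"), _toy_edge("d", "e")},
        core | {_toy_edge("c", "d")},
        core,
    ]
    result = consensus(nets)
    assert result.edge_weights[_toy_edge("a", "b")] == 4
    assert result.edge_weights[_toy_edge("c", "d")] == 3
    assert result.edge_weights[_toy_edge("e", "f")] == 1
    assert result.consensus_components == [{"a", "b", "c"}]
    assert result.consensus_genes == {"a", "b", "c"}
    # extension attaches d (weight 3), then e (weight 2), then f (weight 1)
    assert result.extended_components == [{"a", "b", "c", "d", "e", "f"}]
    assert result.regulated_genes == {"a", "b", "c", "d", "e", "f"}
    # functional modules drop the weight-1 edge, so f is excluded
    assert result.functional_components == [{"a", "b", "c", "d", "e"}]


def test_consensus_identical_networks_are_idempotent():
    edges = {_toy_edge("x", "y"), _toy_edge("y", "z"), _toy_edge("p", "q")}
    result = consensus([edges] * 4)
    assert all(w == 4 for w in result.edge_weights.values())
    assert sorted(map(sorted, result.consensus_components)) == [
        ["p", "q"], ["x", "y", "z"]
    ]
    assert result.consensus_components == result.extended_components
    with pytest.raises(ValueError):
        consensus([])
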