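"""Insulated heat diffusion on PPI networks and hot-module extraction.

Gene heats (|z*| methylation-expression correlations) are diffused over a
protein-protein interaction network with an insulated random walk: each
node keeps a fraction ``beta`` of its heat per step and pushes the rest to
its neighbors through the degree-normalized walk matrix ``W`` (column
``j`` spreads ``1/deg(j)`` to each neighbor).  The closed form of the
process is

    F = beta * (I - (1 - beta) * W)^(-1)

whose column ``j`` is how node ``j``'s unit heat distributes at steady
state (columns sum to one).  The exchanged-heat matrix ``E = F @ diag(h)``
gives the heat node ``i`` receives from source ``j``; thresholding ``E`` at
``delta`` yields a directed graph whose strongly connected components of
size >= 2 are the candidate modules.

``delta`` is chosen on degree-preserving random networks (smallest
threshold keeping all components at or below ``L_max``, median over
networks, smallest significant candidate), and component-size significance
comes from permuting the heat values over the network's genes.  Runs on
four reference networks are combined by edge-consensus weights 1-4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

Edge = tuple[Hashable, Hashable]


def _undirected(u: Hashable, v: Hashable) -> Edge:
    return (u, v) if u <= v else (v, u)


# ---------------------------------------------------------------------------
# diffusion core
# ---------------------------------------------------------------------------

def walk_matrix(graph: nx.Graph, nodes: Sequence[Hashable] | None = None) -> np.ndarray:
    """Column-stochastic degree-normalized walk matrix of a simple graph.

    ``W[i, j] = 1/deg(j)`` if {i, j} is an edge.  Isolated nodes and
    self-loops must have been removed upstream.
    """
    nodes = list(nodes) if nodes is not None else sorted(graph.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    w = np.zeros((n, n))
    for node in nodes:
        deg = graph.degree(node)
        if deg == 0:
            raise ValueError(f"isolated node {node!r}: remove before diffusion")
        j = index[node]
        for nb in graph.neighbors(node):
            if nb == node:
                raise ValueError(f"self-loop at {node!r}: remove before diffusion")
            w[index[nb], j] = 1.0 / deg
    return w


def diffusion(w: np.ndarray, beta: float) -> np.ndarray:
    """Insulated-diffusion matrix ``F = beta (I - (1-beta) W)^(-1)``."""
    if not 0 < beta < 1:
        raise ValueError(f"beta must be in (0, 1), got {beta}")
    w = np.asarray(w, dtype=np.float64)
    n = w.shape[0]
    try:
        f = beta * np.linalg.solve(np.eye(n) - (1.0 - beta) * w, np.eye(n))
    except np.linalg.LinAlgError as err:  # cannot occur for stochastic W
        raise np.linalg.LinAlgError(f"diffusion system singular: {err}") from err
    return f


def diffusion_series(w: np.ndarray, beta: float, n_terms: int = 200) -> np.ndarray:
    """Truncated power series ``beta * sum_t (1-beta)^t W^t``.

    Independent cross-check of :func:`diffusion`; converges geometrically.
    """
    w = np.asarray(w, dtype=np.float64)
    n = w.shape[0]
    term = np.eye(n)
    total = np.eye(n).copy()
    for _ in range(1, n_terms):
        term = (1.0 - beta) * (w @ term)
        total += term
    return beta * total


def heat_vector(
    heat: Mapping[Hashable, float], nodes: Sequence[Hashable]
) -> np.ndarray:
    """Align a gene -> heat mapping to a node order; missing genes get 0."""
    h = np.array([float(heat.get(n, 0.0)) for n in nodes])
    if np.any(h < 0):
        raise ValueError("heat values must be nonnegative")
    return h


def exchanged_heat(f: np.ndarray, h: np.ndarray) -> np.ndarray:
    """``E = F @ diag(h)``: heat received by row node from column source."""
    f = np.asarray(f, dtype=np.float64)
    h = np.asarray(h, dtype=np.float64)
    if h.shape != (f.shape[1],):
        raise ValueError(f"heat length {h.shape} does not match F {f.shape}")
    return f * h[np.newaxis, :]


# ---------------------------------------------------------------------------
# subnetwork extraction
# ---------------------------------------------------------------------------

@dataclass
class SubnetworkSet:
    """Strongly connected components of the delta-thresholded heat graph."""

    components: list[set]
    edges: list[set[Edge]]  # undirected internal edges, aligned to components
    delta: float

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.components]

    def edge_set(self) -> set[Edge]:
        out: set[Edge] = set()
        for es in self.edges:
            out |= es
        return out

    def gene_set(self) -> set:
        out: set = set()
        for c in self.components:
            out |= c
        return out


def _component_labels(e: np.ndarray, delta: float) -> tuple[int, np.ndarray]:
    """Strong components of the graph with edge j->i iff E[i,j] >= delta."""
    adj = e >= delta
    np.fill_diagonal(adj, False)
    # csgraph convention: entry [i, j] is edge i->j, so transpose
    csr = sparse.csr_matrix(adj.T)
    return connected_components(csr, directed=True, connection="strong")


def scc_sizes(e: np.ndarray, delta: float) -> list[int]:
    """Sizes (>= 2) of strongly connected components at threshold delta."""
    n_comp, labels = _component_labels(e, delta)
    counts = np.bincount(labels, minlength=n_comp)
    return sorted((int(c) for c in counts if c >= 2), reverse=True)


def extract_subnetworks(
    e: np.ndarray, delta: float, nodes: Sequence[Hashable]
) -> SubnetworkSet:
    """Modules: strong components (size >= 2) of the thresholded heat graph."""
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    e = np.asarray(e, dtype=np.float64)
    nodes = list(nodes)
    n_comp, labels = _component_labels(e, delta)
    members: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        members.setdefault(int(lab), []).append(idx)
    adj = e >= delta
    np.fill_diagonal(adj, False)
    components, edges = [], []
    for lab in sorted(members, key=lambda c: (-len(members[c]), min(members[c]))):
        idxs = members[lab]
        if len(idxs) < 2:
            continue
        comp = {nodes[i] for i in idxs}
        es: set[Edge] = set()
        for i in idxs:
            for j in idxs:
                if i != j and adj[i, j]:  # heat from j received by i
                    es.add(_undirected(nodes[i], nodes[j]))
        components.append(comp)
        edges.append(es)
    return SubnetworkSet(components=components, edges=edges, delta=delta)


def delta_min(e: np.ndarray, l_max: int) -> float:
    """Smallest threshold keeping every strong component at size <= l_max.

    The component sizes are a step function of delta with breakpoints at
    the distinct off-diagonal entries of E, so the search is a binary
    search over those entries.
    """
    e = np.asarray(e, dtype=np.float64)
    off = e[~np.eye(e.shape[0], dtype=bool)]
    values = np.unique(off[off > 0])
    if values.size == 0:
        return np.finfo(float).tiny
    if max(scc_sizes(e, values[0]), default=0) <= l_max:
        return float(values[0])
    lo, hi = 0, values.size - 1  # condition False at lo, seek smallest True
    if max(scc_sizes(e, values[hi]), default=0) > l_max:
        return float(values[hi] * (1 + 1e-12) + np.finfo(float).tiny)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if max(scc_sizes(e, values[mid]), default=0) <= l_max:
            hi = mid
        else:
            lo = mid
    return float(values[hi])


# ---------------------------------------------------------------------------
# parameter selection
# ---------------------------------------------------------------------------

def select_beta(
    graph: nx.Graph,
    beta_grid: Sequence[float] | None = None,
    source: Hashable | None = None,
) -> float:
    """Pick the insulation parameter from the level-one retention curve.

    For each beta, diffuse unit heat from a high-betweenness source and
    measure, over a threshold grid, how many direct neighbors keep an
    influence above the threshold.  The curve plateaus at the source degree
    and drops once the threshold passes the weakest direct neighbor; the
    drop point theta(beta) is that weakest level-one influence.  The chosen
    beta maximizes theta(beta): the largest insulation that still keeps all
    direct neighbors clearly heated.
    """
    beta_grid = list(beta_grid) if beta_grid is not None else [
        round(0.05 * k, 2) for k in range(1, 20)
    ]
    if len(beta_grid) == 1:
        return float(beta_grid[0])
    if not nx.is_connected(graph):
        raise ValueError("beta selection expects a connected network")
    nodes = sorted(graph.nodes())
    if source is None:
        bc = nx.betweenness_centrality(graph)
        source = max(sorted(bc), key=lambda n: bc[n])
    level_one = sorted(graph.neighbors(source))
    if not level_one or len(level_one) >= len(nodes) - 1:
        warnings.warn(
            "degenerate topology for beta selection; returning default 0.5",
            stacklevel=2,
        )
        return 0.5
    index = {n: i for i, n in enumerate(nodes)}
    w = walk_matrix(graph, nodes)
    n = len(nodes)
    e_src = np.zeros(n)
    e_src[index[source]] = 1.0
    l1_idx = np.array([index[v] for v in level_one])

    thetas = []
    for beta in beta_grid:
        col = beta * np.linalg.solve(np.eye(n) - (1 - beta) * w, e_src)
        influences = col[l1_idx]
        # drop point of the level-one count curve = weakest neighbor influence
        grid = np.sort(np.unique(influences))
        plateau = int((influences > 0).sum())
        drop = grid[0]
        for theta in grid:
            if int((influences > theta * (1 - 1e-12)).sum()) < plateau:
                drop = theta
                break
        thetas.append(float(drop))
    if np.ptp(thetas) < 1e-15:
        warnings.warn(
            "level-one drop point flat across the beta grid; returning 0.5",
            stacklevel=2,
        )
        return 0.5
    best = int(np.argmax(thetas))
    return float(beta_grid[best])


def random_network(
    graph: nx.Graph,
    seed: int | np.random.Generator | None = None,
    n_swaps: int | None = None,
) -> nx.Graph:
    """Degree-preserving randomization by repeated double edge swaps.

    Keeps the degree sequence exactly; produces no self-loops or parallel
    edges.  Default number of attempted swaps is 10x the edge count.
    """
    g = graph.copy()
    m = g.number_of_edges()
    if n_swaps is None:
        n_swaps = 10 * m
    if n_swaps == 0 or m < 2:
        return g
    try:
        nx.double_edge_swap(g, nswap=n_swaps, max_tries=100 * n_swaps, seed=seed)
    except nx.NetworkXAlgorithmError:
        pass  # rigid graphs (e.g. triangles) admit no swaps
    except nx.NetworkXError:
        pass
    return g


@dataclass
class SignificanceResult:
    """Observed counts X_k of components of size >= k with permutation p."""

    x_k: dict[int, int]
    p_values: dict[int, float]
    n_perm: int


def _x_k(sizes: Sequence[int], k_values: Sequence[int]) -> np.ndarray:
    sizes = np.asarray(sizes if len(sizes) else [0])
    return np.array([(sizes >= k).sum() for k in k_values])


def significance_test(
    graph: nx.Graph,
    heat: Mapping[Hashable, float],
    beta: float,
    delta: float,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    f: np.ndarray | None = None,
    nodes: Sequence[Hashable] | None = None,
) -> SignificanceResult:
    """Permutation significance of the observed component-size statistics.

    ``X_k`` is the number of components of size >= k.  Heat values are
    shuffled over all network genes (zeros included) ``n_perm`` times;
    ``p(k)`` is the fraction of permutations with a statistic at least as
    large as observed.
    """
    if n_perm <= 0:
        raise ValueError("need a positive number of permutations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nodes = list(nodes) if nodes is not None else sorted(graph.nodes())
    if f is None:
        f = diffusion(walk_matrix(graph, nodes), beta)
    h = heat_vector(heat, nodes)
    obs_sizes = scc_sizes(exchanged_heat(f, h), delta)
    k_max = max(obs_sizes, default=2)
    k_values = list(range(2, k_max + 1))
    obs_x = _x_k(obs_sizes, k_values)
    exceed = np.zeros(len(k_values))
    for _ in range(n_perm):
        perm_sizes = scc_sizes(exchanged_heat(f, rng.permutation(h)), delta)
        exceed += _x_k(perm_sizes, k_values) >= obs_x
    return SignificanceResult(
        x_k={k: int(x) for k, x in zip(k_values, obs_x)},
        p_values={k: float(c / n_perm) for k, c in zip(k_values, exceed)},
        n_perm=n_perm,
    )


@dataclass
class DeltaSelection:
    delta: float
    candidates: dict[int, float]  # L_max -> median delta_min over random nets
    significance: dict[float, SignificanceResult] = field(default_factory=dict)


def select_delta(
    graph: nx.Graph,
    heat: Mapping[Hashable, float],
    beta: float,
    l_max_list: Sequence[int] = (5, 10, 15, 20),
    n_random: int = 100,
    n_perm: int = 100,
    alpha: float = 0.05,
    k_cap: int = 10,
    seed: int | None = None,
) -> DeltaSelection:
    """Edge threshold from degree-preserving random networks.

    For each random network the smallest delta keeping all components at
    size <= L_max is found; the median over networks is the candidate for
    that L_max.  The selected candidate is the one whose observed
    component sizes are most significant on the real network -- the
    largest count of sizes k (2 <= k <= k_cap; larger components are too
    rare for a stable permutation count) with p(k) < alpha -- with ties
    broken toward the smallest delta.  If no candidate reaches
    significance, the smallest is returned with a warning.
    """
    rng = np.random.default_rng(seed)
    nodes = sorted(graph.nodes())
    minima: dict[int, list[float]] = {l: [] for l in l_max_list}
    for _ in range(n_random):
        g_rand = random_network(graph, seed=int(rng.integers(2**31 - 1)))
        f_rand = diffusion(walk_matrix(g_rand, nodes), beta)
        e_rand = exchanged_heat(f_rand, heat_vector(heat, nodes))
        for l_max in l_max_list:
            minima[l_max].append(delta_min(e_rand, l_max))
    candidates = {l: float(np.median(v)) for l, v in minima.items()}

    f_real = diffusion(walk_matrix(graph, nodes), beta)
    selection = DeltaSelection(delta=np.nan, candidates=candidates)
    scored: list[tuple[int, float]] = []
    for cand in sorted(set(candidates.values())):
        sig = significance_test(
            graph, heat, beta, cand, n_perm=n_perm,
            seed=int(rng.integers(2**31 - 1)), f=f_real, nodes=nodes,
        )
        selection.significance[cand] = sig
        n_sig = sum(
            1 for k, p in sig.p_values.items() if k <= k_cap and p < alpha
        )
        scored.append((n_sig, cand))
    best_n, chosen = max(scored, key=lambda t: (t[0], -t[1]))
    if best_n == 0:
        warnings.warn(
            "no candidate delta reached significance; using the smallest",
            stacklevel=2,
        )
        chosen = min(candidates.values())
    selection.delta = float(chosen)
    return selection


# ---------------------------------------------------------------------------
# cross-network consensus
# ---------------------------------------------------------------------------

@dataclass
class ConsensusResult:
    """Cross-network agreement of per-network module runs (weights 1-4)."""

    edge_weights: dict[Edge, int]
    consensus_components: list[set]
    extended_components: list[set]
    functional_components: list[set]

    @property
    def consensus_genes(self) -> set:
        out: set = set()
        for c in self.consensus_components:
            out |= c
        return out

    @property
    def regulated_genes(self) -> set:
        out: set = set()
        for c in self.extended_components:
            out |= c
        return out


def _components_of_edges(edges: Sequence[Edge]) -> list[set]:
    g = nx.Graph()
    g.add_edges_from(edges)
    return [set(c) for c in nx.connected_components(g)]


def _grow(components: list[set], edges: Sequence[Edge]) -> list[set]:
    """Attach genes reachable from a component through the given edges."""
    comps = [set(c) for c in components]
    changed = True
    while changed:
        changed = False
        for u, v in edges:
            for comp in comps:
                if (u in comp) != (v in comp):
                    comp.update((u, v))
                    changed = True
        # merge components that came to overlap
        merged: list[set] = []
        for comp in comps:
            for m in merged:
                if m & comp:
                    m |= comp
                    break
            else:
                merged.append(comp)
        comps = merged
    return comps


def consensus(
    network_edge_sets: Sequence[set[Edge]],
    min_functional_size: int = 3,
) -> ConsensusResult:
    """Combine module edges from several reference networks.

    Each edge gets a weight = number of networks reporting it.  Consensus
    components are connected components of the full-agreement (weight = N)
    edges; they are then extended by attaching genes reachable through
    weight N-1, then N-2, ... then weight-1 edges.  Functional modules are
    the extended components after deleting weight-1 edges, keeping those
    with at least ``min_functional_size`` genes.
    """
    n = len(network_edge_sets)
    if n == 0:
        raise ValueError("need at least one network result")
    weights: dict[Edge, int] = {}
    for edge_set in network_edge_sets:
        for u, v in edge_set:
            e = _undirected(u, v)
            weights[e] = weights.get(e, 0) + 1

    by_weight: dict[int, list[Edge]] = {}
    for e, w in weights.items():
        by_weight.setdefault(w, []).append(e)
    for w in by_weight:
        by_weight[w].sort()

    consensus_comps = _components_of_edges(by_weight.get(n, []))
    extended = [set(c) for c in consensus_comps]
    for w in range(n - 1, 0, -1):
        extended = _grow(extended, by_weight.get(w, []))

    regulated = set().union(*extended) if extended else set()
    heavy_edges = [
        e for e, w in weights.items()
        if w >= 2 and e[0] in regulated and e[1] in regulated
    ]
    functional = [
        c for c in _components_of_edges(heavy_edges)
        if len(c) >= min_functional_size
    ]

    def _key(comps: list[set]) -> list[set]:
        return sorted(comps, key=lambda c: (-len(c), sorted(map(str, c))))

    return ConsensusResult(
        edge_weights=weights,
        consensus_components=_key(consensus_comps),
        extended_components=_key(extended),
        functional_components=_key(functional),
    )
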