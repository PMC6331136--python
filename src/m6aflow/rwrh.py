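"""Random walk with restart on a gene-disease heterogeneous network.

The heterogeneous network joins a gene interaction layer and a disease
similarity layer through gene-disease relations.  A walker restarts at the
seed distribution (significant m6A-regulated genes and their annotated
diseases) with probability ``gamma`` per step; at a node with cross-layer
links it jumps layers with probability ``lambda``; the initial mass puts
``eta`` on the disease seeds.  The steady-state disease probabilities rank
candidate m6A-associated diseases; a top-10 call is assessed against
degree-preserving random gene networks (with seed-gene/disease relations
removed) to obtain an empirical p-value, and only diseases significant in
all reference networks are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .diffusion import random_network


@dataclass(frozen=True)
class RWRHConfig:
    """Walk parameters (the standard convention of the cited method)."""

    gamma: float = 0.7  # restart probability
    lam: float = 0.5  # layer-jump probability
    eta: float = 0.5  # initial mass on the disease seeds
    similarity_floor: float = 0.3  # drop weaker disease-disease edges
    tol: float = 1e-10
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        for name in ("gamma", "lam", "eta"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


@dataclass
class HeterogeneousNetwork:
    """Gene layer + disease similarity layer + bipartite gene-disease links."""

    gene_graph: nx.Graph
    disease_similarity: pd.DataFrame  # symmetric, weights in [0, 1]
    gene_disease: set[tuple[Hashable, Hashable]]

    def __post_init__(self) -> None:
        sim = self.disease_similarity
        if list(sim.index) != list(sim.columns):
            raise ValueError("similarity matrix must be square with matching ids")
        if not np.allclose(sim.values, sim.values.T, atol=1e-9):
            raise ValueError("disease similarity must be symmetric")
        genes = set(self.gene_graph.nodes())
        diseases = set(sim.index)
        if genes & diseases:
            raise ValueError("gene and disease id sets must be disjoint")
        for g, d in self.gene_disease:
            if g in diseases or d in genes:
                raise ValueError(f"relation ({g}, {d}) crosses id namespaces")


@dataclass
class RWRHResult:
    p_gene: pd.Series
    p_disease: pd.Series
    n_iter: int
    residual: float


@dataclass(frozen=True)
class DiseaseCall:
    disease: Hashable
    rank: int
    probability: float
    empirical_p: float | None = None

    @property
    def significant(self) -> bool:
        return self.empirical_p is not None and self.empirical_p < 0.05


def build_transition(
    network: HeterogeneousNetwork, cfg: RWRHConfig | None = None
) -> tuple[np.ndarray, list, list]:
    """Column-stochastic transition matrix over genes then diseases.

    A column with cross-layer links sends ``lambda`` of its mass across
    (split by link weight) and walks its own layer with the rest; without
    cross links all mass stays within the layer.  Nodes isolated in both
    senses are dropped with a warning.
    """
    cfg = cfg or RWRHConfig()
    sim = network.disease_similarity.copy()
    sim.values[sim.values < cfg.similarity_floor] = 0.0
    np.fill_diagonal(sim.values, 0.0)

    genes = sorted(network.gene_graph.nodes())
    diseases = sorted(sim.index)
    links_g: dict[Hashable, list] = {g: [] for g in genes}
    links_d: dict[Hashable, list] = {d: [] for d in diseases}
    for g, d in network.gene_disease:
        if g in links_g and d in links_d:
            links_g[g].append(d)
            links_d[d].append(g)

    def _isolated(node, layer_deg, links):
        return layer_deg == 0 and not links

    drop_g = [g for g in genes if _isolated(g, network.gene_graph.degree(g), links_g[g])]
    drop_d = [
        d for d in diseases
        if _isolated(d, float(sim.loc[d].sum()), links_d[d])
    ]
    if drop_g or drop_d:
        warnings.warn(
            f"dropping {len(drop_g)} isolated genes and "
            f"{len(drop_d)} isolated diseases",
            stacklevel=2,
        )
        genes = [g for g in genes if g not in set(drop_g)]
        diseases = [d for d in diseases if d not in set(drop_d)]
    if not network.gene_disease:
        warnings.warn(
            "no gene-disease relations: layers walk independently",
            stacklevel=2,
        )

    gi = {g: i for i, g in enumerate(genes)}
    di = {d: i for i, d in enumerate(diseases)}
    ng, nd = len(genes), len(diseases)
    m = np.zeros((ng + nd, ng + nd))

    for g in genes:
        j = gi[g]
        nbrs = [v for v in network.gene_graph.neighbors(g) if v in gi]
        cross = [d for d in links_g[g] if d in di]
        jump = cfg.lam if (cross and nbrs) else (1.0 if cross else 0.0)
        for d in cross:
            m[ng + di[d], j] = jump / len(cross)
        for v in nbrs:
            m[gi[v], j] = (1.0 - jump) / len(nbrs)

    for d in diseases:
        j = di[d]
        weights = sim.loc[:, d]
        wsum = float(weights.sum())
        cross = [g for g in links_d[d] if g in gi]
        jump = cfg.lam if (cross and wsum > 0) else (1.0 if cross else 0.0)
        for g in cross:
            m[gi[g], ng + j] = jump / len(cross)
        if wsum > 0:
            for other, w in weights.items():
                if w > 0:
                    m[ng + di[other], ng + j] = (1.0 - jump) * w / wsum
    return m, genes, diseases


def rwrh(
    network: HeterogeneousNetwork,
    gene_seeds: Iterable[Hashable],
    disease_seeds: Iterable[Hashable],
    cfg: RWRHConfig | None = None,
    transition: tuple[np.ndarray, list, list] | None = None,
) -> RWRHResult:
    """Iterate ``p <- (1-gamma) M p + gamma p0`` to the steady state.

    ``p0`` puts ``eta`` mass uniformly on the disease seeds and ``1-eta``
    on the gene seeds (all mass on one side if the other has no seeds).
    """
    cfg = cfg or RWRHConfig()
    m, genes, diseases = transition or build_transition(network, cfg)
    gi = {g: i for i, g in enumerate(genes)}
    di = {d: i for i, d in enumerate(diseases)}
    g_idx = sorted(gi[g] for g in set(gene_seeds) if g in gi)
    d_idx = sorted(di[d] for d in set(disease_seeds) if d in di)
    if not g_idx and not d_idx:
        raise ValueError("no seed maps into the network")
    ng = len(genes)
    p0 = np.zeros(ng + len(diseases))
    eta = cfg.eta if (g_idx and d_idx) else (1.0 if d_idx else 0.0)
    if d_idx:
        p0[[ng + i for i in d_idx]] = eta / len(d_idx)
    if g_idx:
        p0[g_idx] = (1.0 - eta) / len(g_idx)

    p = p0.copy()
    for it in range(1, cfg.max_iter + 1):
        p_next = (1.0 - cfg.gamma) * (m @ p) + cfg.gamma * p0
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        if residual < cfg.tol:
            return RWRHResult(
                p_gene=pd.Series(p[:ng], index=genes),
                p_disease=pd.Series(p[ng:], index=diseases),
                n_iter=it,
                residual=residual,
            )
    raise RuntimeError(
        f"RWRH did not converge in {cfg.max_iter} iterations "
        f"(residual {residual:.3e})"
    )


def rank_diseases(
    result: RWRHResult,
    top_k: int = 10,
    exclude_seeds: bool = False,
    seed_diseases: Iterable[Hashable] = (),
) -> list[DiseaseCall]:
    """Top diseases by steady-state probability; ties break by disease id."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    probs = result.p_disease
    if exclude_seeds:
        probs = probs.drop(index=[d for d in set(seed_diseases) if d in probs.index])
    order = sorted(probs.index, key=lambda d: (-probs[d], str(d)))
    return [
        DiseaseCall(disease=d, rank=i + 1, probability=float(probs[d]))
        for i, d in enumerate(order[:top_k])
    ]


def empirical_pvalues(
    candidates: Sequence[DiseaseCall],
    network: HeterogeneousNetwork,
    gene_seeds: Iterable[Hashable],
    disease_seeds: Iterable[Hashable],
    cfg: RWRHConfig | None = None,
    n_random: int = 100,
    top_k: int = 10,
    exclude_seeds: bool = False,
    seed: int | None = None,
) -> list[DiseaseCall]:
    """Empirical p for each candidate against random-network nulls.

    Each null rewires the gene layer degree-preservingly and removes the
    relations between seed genes and their diseases, so the null network
    holds no prior tie between the regulated genes and any disease.
    ``p(d)`` is the fraction of nulls in which ``d`` is again in the top-k.
    """
    cfg = cfg or RWRHConfig()
    rng = np.random.default_rng(seed)
    gene_seeds = set(gene_seeds)
    disease_seeds = set(disease_seeds)
    counts = {c.disease: 0 for c in candidates}
    for _ in range(n_random):
        g_rand = random_network(
            network.gene_graph, seed=int(rng.integers(2**31 - 1))
        )
        relations = {
            (g, d) for g, d in network.gene_disease if g not in gene_seeds
        }
        null_net = HeterogeneousNetwork(
            gene_graph=g_rand,
            disease_similarity=network.disease_similarity,
            gene_disease=relations,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = rwrh(null_net, gene_seeds, disease_seeds, cfg)
        top = {
            c.disease
            for c in rank_diseases(
                res, top_k=top_k, exclude_seeds=exclude_seeds,
                seed_diseases=disease_seeds,
            )
        }
        for d in counts:
            if d in top:
                counts[d] += 1
    return [
        DiseaseCall(
            disease=c.disease,
            rank=c.rank,
            probability=c.probability,
            empirical_p=counts[c.disease] / n_random,
        )
        for c in candidates
    ]


def intersect_networks(
    significant_calls: Sequence[Iterable[Hashable]],
) -> list[Hashable]:
    """Diseases significant in every reference network (sorted by id)."""
    if len(significant_calls) == 0:
        raise ValueError("need at least one network's calls")
    sets = [set(calls) for calls in significant_calls]
    final = set.intersection(*sets)
    return sorted(final, key=str)
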