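"""Synthetic fixtures for every pipeline stage.

The generators emulate the shapes of the real inputs -- transcripts with
planted DRACH sites, MeRIP-seq IP coverage with a centered enrichment bump
over methylated adenosines, multi-sample methylation/expression pairs with
a planted correlation, overlapping PPI networks with a planted hot module,
and a gene-disease layer with one planted associated disease -- while
keeping every position, label and parameter in an explicit truth table.

All generators are pure functions of (config, seed): the same seed yields
identical output across runs.  What the fixtures deliberately do *not*
model (read-level noise, isoforms, genome coordinates) is documented in
the package methods note.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import networkx as nx
import numpy as np
import pandas as pd

from .encoding import CandidateSample, HALF_WINDOW

#: all 18 DRACH 5-mers
DRACH_MOTIFS = [
    "".join(m) for m in product("AGU", "AG", "A", "C", "ACU")
]

# fixed flanking consensus carried by positive sites (the learnable
# sequence signal beyond the DRACH motif itself)
_FLANK_LEFT = "GGCGG"  # occupies center-7 .. center-3
_FLANK_RIGHT = "CCUCC"  # occupies center+3 .. center+7


@dataclass
class SimulationConfig:
    """Knobs of every generator; defaults are the package's study conditions."""

    # -- transcriptome / training set
    n_positive_sites: int = 700
    n_negative_sites: int = 2100  # 1:3 imbalance, split over ensemble members
    transcript_length: int = 1300
    sites_per_transcript: int = 10
    min_site_spacing: int = 120  # > 2x the 50-nt exclusion radius
    seq_signal_strength: float = 0.35  # per-base flank consensus probability
    # -- IP coverage
    background_rate: float = 10.0  # Poisson background per base
    bump_amplitude: float = 60.0  # added rate at a methylated center
    bump_width: float = 10.0  # Gaussian sd of the enrichment bump, nt
    peak_halfwidth: int = 60
    rc_total: int = 10_000_000
    # -- multi-sample correlation
    n_genes: int = 500
    n_samples: int = 20
    planted_rho: float = 0.8
    rho_positive_fraction: float = 0.5  # remaining genes get rho = 0
    min_occurrence: int = 12
    # -- PPI networks
    network_size: int = 200
    edge_prob: float = 0.04
    module_size: int = 8
    module_edge_prob: float = 0.9
    n_networks: int = 4
    background_keep_prob: float = 0.7
    module_heat: tuple[float, float] = (1.5, 2.5)  # uniform range
    background_heat_scale: float = 0.25  # half-normal scale for warm genes
    background_heat_fraction: float = 0.25  # genes with any heat at all
    # -- disease layer
    n_decoy_diseases: int = 30
    n_cluster_diseases: int = 18  # seed-linked diseases in a similarity block
    planted_gene_links: int = 8  # the planted disease annotates the module
    cluster_similarity: float = 0.6

    def __post_init__(self) -> None:
        if self.transcript_length < 101:
            raise ValueError("transcripts must be at least 101 nt")
        if not -1 < self.planted_rho < 1:
            raise ValueError("planted correlation must be in (-1, 1)")
        if self.module_size >= self.network_size:
            raise ValueError("module must be smaller than the network")
        if self.n_samples < self.min_occurrence:
            raise ValueError(
                "need at least as many samples as the recurrence cutoff"
            )


# ---------------------------------------------------------------------------
# transcriptome + coverage
# ---------------------------------------------------------------------------

@dataclass
class Transcriptome:
    sequences: dict[str, str]
    truth: pd.DataFrame  # transcript_id, center_pos, motif, label


def _plant_site(
    seq: list[str], pos: int, motif: str, positive: bool,
    signal: float, rng: np.random.Generator,
) -> None:
    seq[pos - 2 : pos + 3] = list(motif)
    if positive and signal > 0:
        for k, base in enumerate(_FLANK_LEFT):
            if rng.random() < signal:
                seq[pos - 7 + k] = base
        for k, base in enumerate(_FLANK_RIGHT):
            if rng.random() < signal:
                seq[pos + 3 + k] = base


def simulate_transcriptome(
    cfg: SimulationConfig | None = None, seed: int | None = None
) -> Transcriptome:
    """Random RNA transcripts with planted positive and negative DRACH sites.

    Sites sit at least ``min_site_spacing`` apart (so negatives are always
    more than 50 nt from any positive, mirroring the labeling rule) and at
    least 55 nt from either transcript end so the 101-nt window always
    fits.  Positives additionally carry a probabilistic flanking consensus
    -- the sequence signal a classifier can learn.
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(seed)
    n_sites = cfg.n_positive_sites + cfg.n_negative_sites
    per_tx = cfg.sites_per_transcript
    needed = 55 + per_tx * cfg.min_site_spacing
    if needed > cfg.transcript_length:
        raise ValueError(
            f"cannot place {per_tx} sites {cfg.min_site_spacing} nt apart "
            f"in a {cfg.transcript_length}-nt transcript"
        )
    labels = np.array(
        ["positive"] * cfg.n_positive_sites + ["negative"] * cfg.n_negative_sites
    )
    rng.shuffle(labels)

    sequences: dict[str, str] = {}
    rows = []
    site_i = 0
    t = 0
    while site_i < n_sites:
        tx = f"tx{t:04d}"
        t += 1
        seq = list(rng.choice(list("ACGU"), size=cfg.transcript_length))
        pos = 55
        for _ in range(per_tx):
            if site_i >= n_sites:
                break
            jitter = int(rng.integers(0, max(cfg.min_site_spacing // 4, 1)))
            center = pos + jitter
            if center + 55 > cfg.transcript_length:
                break
            motif = DRACH_MOTIFS[rng.integers(len(DRACH_MOTIFS))]
            positive = labels[site_i] == "positive"
            _plant_site(seq, center, motif, positive,
                        cfg.seq_signal_strength, rng)
            rows.append(
                {"transcript_id": tx, "center_pos": center,
                 "motif": motif, "label": labels[site_i]}
            )
            site_i += 1
            pos = center + cfg.min_site_spacing
        sequences[tx] = "".join(seq)
    truth = pd.DataFrame(rows)
    return Transcriptome(sequences=sequences, truth=truth)


def simulate_coverage(
    transcriptome: Transcriptome,
    cfg: SimulationConfig | None = None,
    seed: int | None = None,
    active: pd.Series | None = None,
    amplitude_of: dict[tuple[str, int], float] | None = None,
) -> dict[str, np.ndarray]:
    """Per-base IP read counts: Poisson background plus site-centered bumps.

    Only positive sites (optionally masked by ``active``, a boolean Series
    aligned to the truth table) receive a Gaussian-shaped enrichment bump;
    per-site amplitudes may be overridden with ``amplitude_of`` to couple
    coverage to an expression model.
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(seed)
    rate = {
        tx: np.full(len(seq), cfg.background_rate, dtype=np.float64)
        for tx, seq in transcriptome.sequences.items()
    }
    truth = transcriptome.truth
    for i, row in truth.iterrows():
        if row["label"] != "positive":
            continue
        if active is not None and not bool(active.iloc[i]):
            continue
        amp = cfg.bump_amplitude
        if amplitude_of is not None:
            amp = amplitude_of.get((row["transcript_id"], row["center_pos"]), amp)
        track = rate[row["transcript_id"]]
        span = np.arange(len(track))
        track += amp * np.exp(
            -((span - row["center_pos"]) ** 2) / (2 * cfg.bump_width**2)
        )
    return {tx: rng.poisson(r).astype(np.int64) for tx, r in sorted(rate.items())}


def truth_candidates(
    transcriptome: Transcriptome,
    coverage: dict[str, np.ndarray],
    cfg: SimulationConfig | None = None,
) -> list[CandidateSample]:
    """Labeled candidates extracted directly at the truth-table positions."""
    cfg = cfg or SimulationConfig()
    out = []
    for _, row in transcriptome.truth.iterrows():
        tx, pos = row["transcript_id"], int(row["center_pos"])
        seq = transcriptome.sequences[tx]
        window = slice(pos - HALF_WINDOW, pos + HALF_WINDOW + 1)
        out.append(
            CandidateSample(
                transcript_id=tx, center_pos=pos, motif=row["motif"],
                sequence=seq[window], rc=coverage[tx][window].astype(float),
                rc_total=cfg.rc_total, label=row["label"],
            )
        )
    return out


def simulate_training_set(
    cfg: SimulationConfig | None = None, seed: int | None = None
) -> tuple[list[CandidateSample], Transcriptome, dict[str, np.ndarray]]:
    """Transcriptome + coverage + labeled candidates in one call."""
    cfg = cfg or SimulationConfig()
    root = np.random.SeedSequence(seed)
    s_tx, s_cov = (int(s.generate_state(1)[0] % 2**31) for s in root.spawn(2))
    transcriptome = simulate_transcriptome(cfg, seed=s_tx)
    coverage = simulate_coverage(transcriptome, cfg, seed=s_cov)
    return truth_candidates(transcriptome, coverage, cfg), transcriptome, coverage


# ---------------------------------------------------------------------------
# multi-sample methylation / expression
# ---------------------------------------------------------------------------

@dataclass
class MultiSampleData:
    methylation: pd.DataFrame  # genes x samples, ln-scale methylation degree
    fpkm: pd.DataFrame  # genes x samples, expression in FPKM
    occurrence: pd.DataFrame  # genes x samples, bool: site called here
    rho: pd.Series  # planted correlation per gene


def simulate_multisample(
    cfg: SimulationConfig | None = None, seed: int | None = None
) -> MultiSampleData:
    """Bivariate-normal (Methlevel, ln FPKM) pairs with planted correlation.

    Half the genes (``rho_positive_fraction``) carry the planted
    correlation, the rest are null.  Per gene, the site is "called" in a
    random subset of samples of size between ``min_occurrence`` and
    ``n_samples``, which controls the per-site n downstream.
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(cfg.n_genes)]
    samples = [f"s{j:02d}" for j in range(cfg.n_samples)]
    n_planted = int(round(cfg.rho_positive_fraction * cfg.n_genes))
    rho = pd.Series(
        [cfg.planted_rho] * n_planted + [0.0] * (cfg.n_genes - n_planted),
        index=genes, name="rho",
    )
    ln_fpkm = rng.normal(2.0, 1.0, size=(cfg.n_genes, cfg.n_samples))
    noise = rng.normal(0.0, 1.0, size=(cfg.n_genes, cfg.n_samples))
    r = rho.values[:, None]
    meth = r * (ln_fpkm - 2.0) + np.sqrt(1.0 - r**2) * noise

    occ = np.zeros((cfg.n_genes, cfg.n_samples), dtype=bool)
    for i in range(cfg.n_genes):
        n_occ = int(rng.integers(cfg.min_occurrence, cfg.n_samples + 1))
        occ[i, rng.choice(cfg.n_samples, size=n_occ, replace=False)] = True

    return MultiSampleData(
        methylation=pd.DataFrame(meth, index=genes, columns=samples),
        fpkm=pd.DataFrame(np.exp(ln_fpkm), index=genes, columns=samples),
        occurrence=pd.DataFrame(occ, index=genes, columns=samples),
        rho=rho,
    )


# ---------------------------------------------------------------------------
# PPI networks with a planted hot module
# ---------------------------------------------------------------------------

@dataclass
class NetworkFixture:
    networks: list[nx.Graph]
    union: nx.Graph
    module: set[str]
    heat: dict[str, float]


def _connect(graph: nx.Graph, rng: np.random.Generator) -> None:
    comps = sorted(nx.connected_components(graph), key=len, reverse=True)
    anchor = sorted(comps[0])
    for comp in comps[1:]:
        u = sorted(comp)[int(rng.integers(len(comp)))]
        v = anchor[int(rng.integers(len(anchor)))]
        graph.add_edge(u, v)


def simulate_networks(
    cfg: SimulationConfig | None = None,
    seed: int | None = None,
    genes: list[str] | None = None,
) -> NetworkFixture:
    """Overlapping reference networks with a planted dense hot module.

    The union graph is Erdos-Renyi background plus a dense ``module_size``
    clique-like module; module edges are present in every derived network,
    background edges are independently subsampled per network (so their
    expected consensus weight is below the maximum).  Module genes get
    heat well above the background half-normal.
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(seed)
    genes = genes or [f"g{i:04d}" for i in range(cfg.network_size)]
    module = set(genes[: cfg.module_size])

    union = nx.Graph()
    union.add_nodes_from(genes)
    for i, u in enumerate(genes):
        for v in genes[i + 1 :]:
            both_mod = u in module and v in module
            p = cfg.module_edge_prob if both_mod else cfg.edge_prob
            if rng.random() < p:
                union.add_edge(u, v)
    if not nx.is_connected(union):
        _connect(union, rng)

    module_edges = {
        e for e in union.edges() if e[0] in module and e[1] in module
    }
    networks = []
    for _ in range(cfg.n_networks):
        g = nx.Graph()
        for u, v in sorted(union.edges()):
            e = (u, v) if u <= v else (v, u)
            if e in module_edges or rng.random() < cfg.background_keep_prob:
                g.add_edge(u, v)
        if not nx.is_connected(g):
            _connect(g, rng)
        networks.append(g)

    # heat is sparse over the network: only "candidate" genes carry any,
    # mirroring a heat table that covers a minority of network genes
    lo, hi = cfg.module_heat
    heat = {}
    for gene in genes:
        if gene in module:
            heat[gene] = float(rng.uniform(lo, hi))
        elif rng.random() < cfg.background_heat_fraction:
            heat[gene] = float(abs(rng.normal(0.0, cfg.background_heat_scale)))
        else:
            heat[gene] = 0.0
    return NetworkFixture(networks=networks, union=union, module=module, heat=heat)


# ---------------------------------------------------------------------------
# gene-disease layer
# ---------------------------------------------------------------------------

@dataclass
class DiseaseFixture:
    similarity: pd.DataFrame
    gene_disease: set[tuple[str, str]]
    planted: str
    cluster: list[str]  # seed-linked diseases forming a similarity block


def simulate_gene_disease(
    network: NetworkFixture,
    cfg: SimulationConfig | None = None,
    seed: int | None = None,
    one_hop: bool = False,
) -> DiseaseFixture:
    """Disease similarity + gene-disease relations with one planted disease.

    Default mode links the planted disease directly to several module
    genes, more than any single competing disease.  A block of
    "cluster" diseases is each linked to one module gene (so the disease
    seed set is sizeable) and shares elevated pairwise similarity; decoys
    link only to random background genes.  In ``one_hop`` mode the planted
    disease has *no* direct module-gene link: it attaches to bridge genes
    adjacent to every module gene and is highly similar to the cluster
    diseases, the topology under which the walk can still surface it.
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(seed)
    module = sorted(network.module)
    background = sorted(set(network.union.nodes()) - network.module)

    planted = "d_planted"
    cluster = [f"d_c{i:02d}" for i in range(cfg.n_cluster_diseases)]
    decoys = [f"d_x{i:02d}" for i in range(cfg.n_decoy_diseases)]
    diseases = [planted] + cluster + decoys
    n = len(diseases)

    sim = rng.uniform(0.0, 0.25, size=(n, n))
    sim = (sim + sim.T) / 2
    df = pd.DataFrame(sim, index=diseases, columns=diseases)
    for i, a in enumerate(cluster):
        for b in cluster[i + 1 :]:
            w = cfg.cluster_similarity + rng.uniform(-0.15, 0.15)
            df.loc[a, b] = df.loc[b, a] = w
    np.fill_diagonal(df.values, 1.0)

    relations: set[tuple[str, str]] = set()
    # each cluster disease annotates one module gene (round-robin)
    for i, d in enumerate(cluster):
        relations.add((module[i % len(module)], d))
    # decoys annotate background genes
    for d in decoys:
        k = int(rng.integers(1, 3))
        for g in rng.choice(background, size=k, replace=False):
            relations.add((str(g), d))

    if one_hop:
        # bridge genes adjacent to every module gene but not in the module
        bridges = []
        candidates = sorted(
            background,
            key=lambda g: -sum(network.union.has_edge(g, m) for m in module),
        )
        for g in candidates[:2]:
            for m in module:
                if not network.union.has_edge(g, m):
                    network.union.add_edge(g, m)
                    for net in network.networks:
                        net.add_edge(g, m)
            bridges.append(g)
        for g in bridges:
            relations.add((g, planted))
        for d in cluster[: max(cfg.n_cluster_diseases // 3, 1)]:
            df.loc[planted, d] = df.loc[d, planted] = 0.8
    else:
        links = rng.choice(module, size=min(cfg.planted_gene_links, len(module)),
                           replace=False)
        for g in links:
            relations.add((str(g), planted))

    return DiseaseFixture(
        similarity=df, gene_disease=relations, planted=planted, cluster=cluster
    )
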