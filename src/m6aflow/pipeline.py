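"""The end-to-end analysis chain on a self-generated fixture.

Stages (each resumable from the previous stage's TSV artifacts):

1. ``simulate``   -- coupled fixture: one transcript per network gene, a
   methylated site per gene whose IP enrichment tracks methylation level
   times expression, multi-sample coverage, four overlapping PPI networks
   with a planted hot module, and a disease layer with a planted disease.
2. ``train``      -- label candidates against the truth table and train
   the balanced CNN ensemble on the training sample.
3. ``predict``    -- score every candidate in every sample; call sites
   above the probability threshold.
4. ``correlate``  -- recurrence filter, methylation degree (window mean of
   de-logged coverage over FPKM), Pearson r -> corrected Fisher z*, gene
   heats.
5. ``hotnet``     -- per network: insulated diffusion, delta selection on
   degree-preserving nulls, component significance by heat permutation.
6. ``consensus``  -- cross-network edge weights, consensus/extended/
   functional modules, the m6A-regulated gene set.
7. ``rwrh``       -- per network: random walk with restart on the
   gene-disease heterogeneous network, top-k candidates, empirical p
   against random-network nulls; final list = intersection over networks.

Every stage draws randomness only from seeds derived from the config seed,
and no artifact embeds a timestamp, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .correlation import (
    correlate_sites, gene_heat, methylation_level, site_recurrence,
)
from .diffusion import (
    consensus, diffusion, exchanged_heat, extract_subnetworks, heat_vector,
    select_delta, significance_test, walk_matrix,
)
from .encoding import HALF_WINDOW, PeakRegion, encode_candidates, label_training
from .encoding import generate_candidates, normalize_reads
from .model import DEFAULT_THRESHOLD, DeepM6AClassifier, call_sites
from .rwrh import (
    HeterogeneousNetwork, RWRHConfig, empirical_pvalues, intersect_networks,
    rank_diseases, rwrh,
)
from .simulate import (
    SimulationConfig, Transcriptome, simulate_coverage,
    simulate_gene_disease, simulate_networks,
)

log = logging.getLogger("m6aflow")

STAGES = (
    "simulate", "train", "predict", "correlate", "hotnet", "consensus", "rwrh"
)


@dataclass
class PipelineConfig:
    """All thresholds, scales and Monte Carlo counts of one pipeline run."""

    seed: int = 0
    # thresholds (study conditions)
    call_threshold: float = DEFAULT_THRESHOLD
    recurrence: int = 12
    alpha: float = 0.05
    top_k: int = 10
    # classifier
    n_members: int = 3
    epochs: int = 30
    batch_size: int = 64
    # fixture scale
    n_genes: int = 200
    transcript_length: int = 400
    n_samples: int = 20
    module_size: int = 8
    module_rho: float = 0.95
    # hot-module discovery
    beta: float = 0.5
    l_max_list: tuple[int, ...] = (5, 10, 15, 20)
    n_random_networks: int = 20
    n_heat_permutations: int = 200
    # disease prioritization
    gamma: float = 0.7
    lam: float = 0.5
    eta: float = 0.5
    similarity_floor: float = 0.3
    n_random_disease: int = 50
    # raw empirical p-values are reported as-is; the optional BH column
    # is off by default
    bh_correction: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.call_threshold < 1:
            raise ValueError("call threshold must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.top_k < 1 or self.recurrence < 1:
            raise ValueError("top_k and recurrence must be positive")

    # -- serialization ----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["l_max_list"] = list(self.l_max_list)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "l_max_list" in data:
            data["l_max_list"] = tuple(data["l_max_list"])
        return cls(**data)

    def digest(self) -> str:
        data = asdict(self)
        data["l_max_list"] = list(self.l_max_list)
        return hashlib.sha256(
            json.dumps(data, sort_keys=True).encode()
        ).hexdigest()[:16]

    def rwrh_config(self) -> RWRHConfig:
        return RWRHConfig(
            gamma=self.gamma, lam=self.lam, eta=self.eta,
            similarity_floor=self.similarity_floor,
        )


def _seed(config: PipelineConfig, stage: str) -> int:
    digest = hashlib.sha256(f"{config.seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _sim_config(config: PipelineConfig) -> SimulationConfig:
    return SimulationConfig(
        network_size=config.n_genes,
        module_size=config.module_size,
        n_samples=config.n_samples,
        transcript_length=config.transcript_length,
    )


# ---------------------------------------------------------------------------
# stage: simulate
# ---------------------------------------------------------------------------

def _gene_of(tx: str) -> str:
    return tx.removeprefix("tx_")


def _pipeline_transcriptome(
    genes: list[str], module: set[str], config: PipelineConfig,
    rng: np.random.Generator,
) -> tuple[Transcriptome, list[PeakRegion]]:
    """One transcript per gene: a positive site flanked by two negatives."""
    from .simulate import DRACH_MOTIFS, _plant_site

    length = config.transcript_length
    centers = {"neg1": 80, "pos": length // 2, "neg2": length - 80}
    sim = _sim_config(config)
    sequences, rows, peaks = {}, [], []
    for gene in genes:
        tx = f"tx_{gene}"
        seq = list(rng.choice(list("ACGU"), size=length))
        for kind, center in centers.items():
            motif = DRACH_MOTIFS[rng.integers(len(DRACH_MOTIFS))]
            positive = kind == "pos"
            _plant_site(seq, center, motif, positive,
                        sim.seq_signal_strength, rng)
            rows.append(
                {"transcript_id": tx, "center_pos": center,
                 "motif": motif,
                 "label": "positive" if positive else "negative"}
            )
            peaks.append(
                PeakRegion(
                    transcript_id=tx,
                    start=max(center - sim.peak_halfwidth, 0),
                    end=min(center + sim.peak_halfwidth + 1, length),
                    gene_id=gene,
                )
            )
        sequences[tx] = "".join(seq)
    return Transcriptome(sequences=sequences, truth=pd.DataFrame(rows)), peaks


def stage_simulate(config: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    sim = _sim_config(config)
    rng = np.random.default_rng(_seed(config, "simulate"))

    networks = simulate_networks(sim, seed=_seed(config, "networks"))
    genes = sorted(networks.union.nodes())
    disease = simulate_gene_disease(networks, sim, seed=_seed(config, "disease"))

    transcriptome, peaks = _pipeline_transcriptome(
        genes, networks.module, config, rng
    )

    # multi-sample expression and methylation targets; module genes carry
    # the planted methylation-expression correlation
    samples = [f"s{j:02d}" for j in range(config.n_samples)]
    rho = np.array([
        config.module_rho if g in networks.module else 0.0 for g in genes
    ])
    ln_fpkm = rng.normal(2.0, 1.0, size=(len(genes), config.n_samples))
    noise = rng.normal(0.0, 1.0, size=(len(genes), config.n_samples))
    meth = rho[:, None] * (ln_fpkm - 2.0) + np.sqrt(1 - rho[:, None] ** 2) * noise
    fpkm = pd.DataFrame(np.exp(ln_fpkm), index=genes, columns=samples)

    occurrence = np.zeros((len(genes), config.n_samples), dtype=bool)
    for i, g in enumerate(genes):
        # module genes are constitutively methylated (called in nearly every
        # sample); background occurrence straddles the recurrence cutoff
        low = (
            max(config.recurrence + 5, 2)
            if g in networks.module
            else max(config.recurrence - 4, 1)
        )
        low = min(low, config.n_samples)  # recurrence above n_samples:
        n_occ = int(rng.integers(low, config.n_samples + 1))  # filter empties
        occurrence[i, rng.choice(config.n_samples, n_occ, replace=False)] = True

    # IP enrichment amplitude ~ methylation level x expression: the window
    # mean of the de-logged normalized coverage then recovers Methlevel
    gauss_mass = float(
        np.exp(-(np.arange(-HALF_WINDOW, HALF_WINDOW + 1) ** 2)
               / (2 * sim.bump_width**2)).mean()
    )
    pos_rows = transcriptome.truth[transcriptome.truth["label"] == "positive"]
    site_of_gene = {
        _gene_of(r["transcript_id"]): (r["transcript_id"], int(r["center_pos"]))
        for _, r in pos_rows.iterrows()
    }

    scale = 80.0  # sets typical center coverage well above background

    # training sample: every positive site active, amplitudes drawn from the
    # same enrichment model as the study samples so the classifier sees the
    # deployment amplitude range during training
    train_amp = {}
    for i, g in enumerate(genes):
        m_t = float(rng.normal(0.0, 1.0))
        fpkm_t = float(np.exp(rng.normal(2.0, 1.0)))
        target = fpkm_t * np.exp(m_t) * scale / 10.0
        train_amp[site_of_gene[g]] = max(
            (target - sim.background_rate) / gauss_mass, 1.0
        )
    cov_train = simulate_coverage(
        transcriptome, sim, seed=_seed(config, "cov_train"),
        amplitude_of=train_amp,
    )
    fio.write_coverage_table(cov_train, outdir / "coverage_train.tsv")
    for j, sample in enumerate(samples):
        active = pd.Series(
            [
                bool(occurrence[genes.index(_gene_of(r["transcript_id"])), j])
                for _, r in transcriptome.truth.iterrows()
            ]
        )
        amplitude = {}
        for i, g in enumerate(genes):
            # window-mean count target: bg + amp * gauss_mass should equal
            # FPKM * exp(meth) * scale / (1e8 / rc_total)
            target = float(fpkm.iloc[i, j] * np.exp(meth[i, j]) * scale / 10.0)
            amp = max((target - sim.background_rate) / gauss_mass, 1.0)
            amplitude[site_of_gene[g]] = amp
        cov = simulate_coverage(
            transcriptome, sim, seed=_seed(config, f"cov_{sample}"),
            active=active, amplitude_of=amplitude,
        )
        fio.write_coverage_table(cov, outdir / f"coverage_{sample}.tsv")

    fio.write_fasta(transcriptome.sequences, outdir / "transcripts.fasta")
    fio.write_bed(peaks, outdir / "peaks.bed")
    transcriptome.truth.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    fio.write_expression(fpkm, outdir / "expression.tsv")
    for k, net in enumerate(networks.networks, 1):
        fio.write_edge_list(net, outdir / f"network_{k}.tsv")
    fio.write_similarity(disease.similarity, outdir / "disease_similarity.tsv")
    fio.write_gene_disease(disease.gene_disease, outdir / "gene_disease.tsv")
    fio.write_json(
        {
            "module": sorted(networks.module),
            "planted_disease": disease.planted,
            "cluster_diseases": disease.cluster,
            "occurrence": {
                g: [samples[j] for j in range(config.n_samples) if occurrence[i, j]]
                for i, g in enumerate(genes)
            },
            "samples": samples,
        },
        outdir / "truth.json",
    )
    log.info("simulate: %d genes, %d samples, module %s",
             len(genes), config.n_samples, sorted(networks.module))


# ---------------------------------------------------------------------------
# stage: train
# ---------------------------------------------------------------------------

def _load_candidates(outdir: Path, coverage_file: str):
    sequences = fio.read_fasta(outdir / "transcripts.fasta")
    peaks = fio.read_bed(outdir / "peaks.bed")
    coverage = fio.read_coverage_table(outdir / coverage_file)
    sim = SimulationConfig()
    return generate_candidates(peaks, sequences, coverage, sim.rc_total)


def stage_train(config: PipelineConfig, outdir: Path) -> None:
    truth = pd.read_csv(outdir / "truth_sites.tsv", sep="\t")
    positives = {
        (r["transcript_id"], int(r["center_pos"]))
        for _, r in truth.iterrows() if r["label"] == "positive"
    }
    candidates = _load_candidates(outdir, "coverage_train.tsv")
    labeled = label_training(candidates, positives)
    fio.write_candidates(labeled, outdir / "training_candidates.tsv")
    y = np.array([1 if c.label == "positive" else 0 for c in labeled])
    X = encode_candidates(labeled)
    clf = DeepM6AClassifier(
        n_members=config.n_members, epochs=config.epochs,
        batch_size=config.batch_size, random_state=_seed(config, "train"),
    )
    clf.fit(X, y)
    clf.save(outdir / "model")
    log.info("train: %d candidates (%d positive)", len(labeled), int(y.sum()))


# ---------------------------------------------------------------------------
# stage: predict
# ---------------------------------------------------------------------------

def stage_predict(config: PipelineConfig, outdir: Path) -> None:
    truth = fio.read_json(outdir / "truth.json")
    samples = truth["samples"]
    clf = DeepM6AClassifier.load(outdir / "model")
    for sample in samples:
        candidates = _load_candidates(outdir, f"coverage_{sample}.tsv")
        probs = clf.predict_proba(encode_candidates(candidates))[:, 1]
        fio.write_predictions(candidates, probs, outdir / f"predictions_{sample}.tsv")
    log.info("predict: scored %d samples", len(samples))


# ---------------------------------------------------------------------------
# stage: correlate
# ---------------------------------------------------------------------------

def stage_correlate(config: PipelineConfig, outdir: Path) -> None:
    truth = fio.read_json(outdir / "truth.json")
    samples = truth["samples"]
    fpkm = fio.read_expression(outdir / "expression.tsv")
    sim = SimulationConfig()

    calls: dict[str, set] = {}
    gene_of_site: dict[tuple, str] = {}
    prob_tables = {}
    for sample in samples:
        df = fio.read_predictions(outdir / f"predictions_{sample}.tsv")
        prob_tables[sample] = df
        called = call_sites(
            {
                (r["chrom"], int(r["start"])): r["probability"]
                for _, r in df.iterrows()
            },
            threshold=config.call_threshold,
        )
        calls[sample] = called
        for _, r in df.iterrows():
            gene_of_site[(r["chrom"], int(r["start"]))] = r["gene_id"]

    occurrences = site_recurrence(calls, gene_of_site, n_min=config.recurrence)
    if not occurrences:
        warnings.warn("no site recurs at the threshold; empty gene table")
        gene_heat({}).to_csv(outdir / "gene_table.tsv", sep="\t")
        fio.write_heat({}, outdir / "heat.tsv")
        return

    needed_samples = sorted({s for occ in occurrences for s in occ.samples})
    coverage_of = {
        s: fio.read_coverage_table(outdir / f"coverage_{s}.tsv")
        for s in needed_samples
    }
    meth_table: dict[tuple, dict[str, float]] = {}
    for occ in occurrences:
        tx, pos = occ.site
        gene = occ.gene_id
        meth_table[occ.site] = {}
        for sample in sorted(occ.samples):
            cov = coverage_of[sample][tx]
            window = cov[pos - HALF_WINDOW : pos + HALF_WINDOW + 1]
            rc_norm = normalize_reads(window, sim.rc_total)
            meth_table[occ.site][sample] = methylation_level(
                rc_norm, float(fpkm.loc[gene, sample])
            )
    expr_table = {g: fpkm.loc[g].to_dict() for g in fpkm.index}
    results = correlate_sites(occurrences, meth_table, expr_table)
    table = gene_heat(results)
    table.to_csv(outdir / "gene_table.tsv", sep="\t")
    fio.write_heat(dict(zip(table.index, table["heat"])), outdir / "heat.tsv")
    log.info("correlate: %d recurrent sites, %d candidate genes",
             len(occurrences), len(table))


# ---------------------------------------------------------------------------
# stage: hotnet
# ---------------------------------------------------------------------------

def _network_paths(outdir: Path) -> list[Path]:
    return sorted(outdir.glob("network_*.tsv"))


def stage_hotnet(config: PipelineConfig, outdir: Path) -> None:
    heat = fio.read_heat(outdir / "heat.tsv")
    for k, path in enumerate(_network_paths(outdir), 1):
        graph = fio.read_edge_list(path)
        if not heat:
            fio.write_json({"delta": None, "components": []},
                           outdir / f"subnetworks_{k}.json")
            continue
        selection = select_delta(
            graph, heat, config.beta, config.l_max_list,
            n_random=config.n_random_networks,
            n_perm=config.n_heat_permutations,
            alpha=config.alpha, seed=_seed(config, f"delta_{k}"),
        )
        nodes = sorted(graph.nodes())
        f = diffusion(walk_matrix(graph, nodes), config.beta)
        e = exchanged_heat(f, heat_vector(heat, nodes))
        subnets = extract_subnetworks(e, selection.delta, nodes)
        sig = significance_test(
            graph, heat, config.beta, selection.delta,
            n_perm=config.n_heat_permutations,
            seed=_seed(config, f"sig_{k}"), f=f, nodes=nodes,
        )
        fio.write_json(
            {
                "delta": selection.delta,
                "candidates": selection.candidates,
                "components": [sorted(c) for c in subnets.components],
                "edges": [sorted(map(list, es)) for es in subnets.edges],
                "x_k": sig.x_k,
                "p_values": sig.p_values,
            },
            outdir / f"subnetworks_{k}.json",
        )
        log.info("hotnet network %d: delta=%.4g, %d components",
                 k, selection.delta, len(subnets.components))


# ---------------------------------------------------------------------------
# stage: consensus
# ---------------------------------------------------------------------------

def stage_consensus(config: PipelineConfig, outdir: Path) -> None:
    edge_sets = []
    for path in sorted(outdir.glob("subnetworks_*.json")):
        data = fio.read_json(path)
        edges = set()
        for es in data.get("edges", []):
            for u, v in es:
                edges.add((u, v) if u <= v else (v, u))
        edge_sets.append(edges)
    result = consensus(edge_sets)
    fio.write_weighted_edges(result.edge_weights, outdir / "pooled_edges.tsv")
    fio.write_json(
        {
            "consensus_components": [sorted(c) for c in result.consensus_components],
            "extended_components": [sorted(c) for c in result.extended_components],
            "functional_components": [sorted(c) for c in result.functional_components],
            "consensus_genes": sorted(result.consensus_genes),
            "regulated_genes": sorted(result.regulated_genes),
        },
        outdir / "consensus.json",
    )
    log.info("consensus: %d regulated genes, %d functional modules",
             len(result.regulated_genes), len(result.functional_components))


# ---------------------------------------------------------------------------
# stage: rwrh
# ---------------------------------------------------------------------------

def stage_rwrh(config: PipelineConfig, outdir: Path) -> None:
    data = fio.read_json(outdir / "consensus.json")
    regulated = set(data["regulated_genes"])
    similarity = fio.read_similarity(outdir / "disease_similarity.tsv")
    relations = fio.read_gene_disease(outdir / "gene_disease.tsv")
    cfg = config.rwrh_config()

    if not regulated:
        warnings.warn("no regulated genes: skipping disease prioritization")
        pd.DataFrame(
            columns=["disease_id", "probability", "rank", "empirical_p",
                     "significant", "network"]
        ).to_csv(outdir / "ranked_diseases.tsv", sep="\t", index=False)
        (outdir / "final_diseases.tsv").write_text("disease_id\n")
        return

    disease_seeds = {d for g, d in relations if g in regulated}
    all_rows = []
    significant_sets = []
    for k, path in enumerate(_network_paths(outdir), 1):
        graph = fio.read_edge_list(path)
        gene_seeds = regulated & set(graph.nodes())
        net = HeterogeneousNetwork(
            gene_graph=graph, disease_similarity=similarity,
            gene_disease=relations,
        )
        result = rwrh(net, gene_seeds, disease_seeds, cfg)
        candidates = rank_diseases(result, top_k=config.top_k)
        candidates = empirical_pvalues(
            candidates, net, gene_seeds, disease_seeds, cfg,
            n_random=config.n_random_disease, top_k=config.top_k,
            seed=_seed(config, f"rwrh_{k}"),
        )
        significant_sets.append(
            {c.disease for c in candidates if c.empirical_p < config.alpha}
        )
        for c in candidates:
            all_rows.append(
                {"disease_id": c.disease, "probability": c.probability,
                 "rank": c.rank, "empirical_p": c.empirical_p,
                 "significant": c.empirical_p < config.alpha, "network": k}
            )
    final = intersect_networks(significant_sets)
    ranked = pd.DataFrame(
        all_rows,
        columns=["disease_id", "probability", "rank", "empirical_p",
                 "significant", "network"],
    )
    if config.bh_correction and len(ranked):
        from scipy.stats import false_discovery_control

        ranked["q_value"] = ranked.groupby("network")["empirical_p"].transform(
            lambda p: false_discovery_control(p, method="bh")
        )
    ranked.to_csv(outdir / "ranked_diseases.tsv", sep="\t", index=False)
    (outdir / "final_diseases.tsv").write_text(
        "disease_id\n" + "".join(f"{d}\n" for d in final)
    )
    log.info("rwrh: final m6A-associated diseases: %s", final)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "train": stage_train,
    "predict": stage_predict,
    "correlate": stage_correlate,
    "hotnet": stage_hotnet,
    "consensus": stage_consensus,
    "rwrh": stage_rwrh,
}

_STAGE_SENTINELS = {
    "simulate": "truth.json",
    "train": "model/ensemble.json",
    "predict": "predictions_s00.tsv",
    "correlate": "heat.tsv",
    "hotnet": "subnetworks_1.json",
    "consensus": "consensus.json",
    "rwrh": "final_diseases.tsv",
}


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    stages: tuple[str, ...] = STAGES,
    resume: bool = False,
) -> Path:
    """Run the requested stages in order; returns the output directory.

    With ``resume`` a stage whose sentinel artifact already exists is
    skipped, so the chain can be restarted from a partial run.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
    config.to_yaml(outdir / "config.yaml")
    fio.write_json(
        {"config_digest": config.digest(), "seed": config.seed,
         "stages": list(stages)},
        outdir / "run_manifest.json",
    )
    for stage in STAGES:
        if stage not in stages:
            continue
        if resume and (outdir / _STAGE_SENTINELS[stage]).exists():
            log.info("stage %s: outputs present, skipping", stage)
            continue
        log.info("stage %s: running", stage)
        _STAGE_FUNCS[stage](config, outdir)
    return outdir
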