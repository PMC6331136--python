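"""Readers and writers for the pipeline's file formats.

FASTA transcripts (``T`` normalized to ``U``), BED6 peak regions (0-based
half-open), per-base IP coverage (bedGraph, per-transcript 2-column TSV,
or pooled 3-column TSV), TSV tables for sites/predictions/expression/heat,
2-column edge lists, disease similarity matrices and JSON truth files.
Malformed lines are rejected with their line number.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .encoding import CandidateSample, PeakRegion, clean_rna


# -- FASTA ------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Transcript id -> RNA sequence (T mapped to U, uppercased)."""
    return {
        rec.id: clean_rna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# -- BED6 -------------------------------------------------------------------

def read_bed(path: str | Path) -> list[PeakRegion]:
    """BED6 (or BED4+) peak regions; start/end 0-based half-open."""
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            if end <= start or start < 0:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            name = fields[3] if len(fields) > 3 else ""
            peaks.append(
                PeakRegion(transcript_id=fields[0], start=start, end=end,
                           gene_id=name)
            )
    return peaks


def write_bed(peaks: Iterable[PeakRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.transcript_id}\t{p.start}\t{p.end}\t{p.gene_id}\t0\t+\n")


# -- coverage ---------------------------------------------------------------

def read_coverage_tsv(path: str | Path, length: int) -> np.ndarray:
    """Per-transcript 2-column TSV (position, count) -> dense count vector."""
    cov = np.zeros(length, dtype=np.int64)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                pos_s, count_s = line.split("\t")
                pos, count = int(pos_s), int(count_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: expected 'pos<TAB>count'") from None
            if not 0 <= pos < length:
                raise ValueError(f"{path}:{lineno}: position {pos} out of range")
            cov[pos] = count
    return cov


def read_bedgraph(path: str | Path, lengths: Mapping[str, int]) -> dict[str, np.ndarray]:
    """bedGraph intervals -> dense per-base count vectors per transcript."""
    tracks = {tx: np.zeros(n, dtype=np.int64) for tx, n in lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph fields")
            tx, start, end, value = (
                fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            )
            if tx not in tracks:
                raise ValueError(f"{path}:{lineno}: unknown transcript {tx!r}")
            if not 0 <= start < end <= lengths[tx]:
                raise ValueError(f"{path}:{lineno}: bad interval [{start}, {end})")
            tracks[tx][start:end] = int(round(value))
    return tracks


def read_coverage_table(path: str | Path) -> dict[str, np.ndarray]:
    """Pooled 3-column TSV (transcript_id, position, count) -> tracks."""
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    out = {}
    for tx, grp in df.groupby("transcript_id", sort=True):
        length = int(grp["position"].max()) + 1
        cov = np.zeros(length, dtype=np.int64)
        cov[grp["position"].to_numpy()] = grp["count"].to_numpy()
        out[str(tx)] = cov
    return out


def write_coverage_table(coverage: Mapping[str, np.ndarray], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {"transcript_id": tx, "position": np.arange(len(cov)), "count": cov}
        )
        for tx, cov in sorted(coverage.items())
    ]
    pd.concat(frames).to_csv(path, sep="\t", index=False)


# -- site / prediction tables ----------------------------------------------

CANDIDATE_COLUMNS = ["transcript_id", "center_pos", "motif", "label"]
PREDICTION_COLUMNS = [
    "chrom", "start", "end", "gene_id", "probability", "strand", "motif"
]


def write_candidates(candidates: Sequence[CandidateSample], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"transcript_id": c.transcript_id, "center_pos": c.center_pos,
             "motif": c.motif, "label": c.label}
            for c in candidates
        ],
        columns=CANDIDATE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_candidates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    missing = set(CANDIDATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_predictions(
    candidates: Sequence[CandidateSample],
    probabilities: Sequence[float],
    path: str | Path,
) -> None:
    """Predicted sites as TSV, one row per candidate, BED-style coordinates."""
    rows = [
        {
            "chrom": c.transcript_id,
            "start": c.center_pos,
            "end": c.center_pos + 1,
            "gene_id": c.gene_id,
            "probability": float(p),
            "strand": "+",
            "motif": c.motif,
        }
        for c, p in zip(candidates, probabilities)
    ]
    pd.DataFrame(rows, columns=PREDICTION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})


# -- expression / heat / networks ------------------------------------------

def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes x samples FPKM table (first column gene_id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(fpkm: pd.DataFrame, path: str | Path) -> None:
    fpkm.to_csv(path, sep="\t", index_label="gene_id")


def read_heat(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return dict(zip(df["gene_id"], df["heat"].astype(float)))


def write_heat(heat: Mapping[str, float], path: str | Path) -> None:
    pd.DataFrame(
        sorted(heat.items()), columns=["gene_id", "heat"]
    ).to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path) -> nx.Graph:
    """2-column TSV edge list -> simple undirected graph (self-loops dropped)."""
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            u, v = fields[0], fields[1]
            if u != v:
                g.add_edge(u, v)
    return g


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(
            (u, v) if u <= v else (v, u) for u, v in graph.edges()
        ):
            fh.write(f"{u}\t{v}\n")


def write_weighted_edges(weights: Mapping[tuple, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for (u, v), w in sorted(weights.items()):
            fh.write(f"{u}\t{v}\t{w}\n")


def read_similarity(path: str | Path) -> pd.DataFrame:
    """Disease similarity from long-form TSV (id_a, id_b, weight)."""
    df = pd.read_csv(path, sep="\t", dtype={"id_a": str, "id_b": str})
    ids = sorted(set(df["id_a"]) | set(df["id_b"]))
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for _, row in df.iterrows():
        mat.loc[row["id_a"], row["id_b"]] = row["weight"]
        mat.loc[row["id_b"], row["id_a"]] = row["weight"]
    np.fill_diagonal(mat.values, 1.0)
    return mat


def write_similarity(similarity: pd.DataFrame, path: str | Path) -> None:
    rows = []
    ids = list(similarity.index)
    for i, a in enumerate(ids):
        for b in ids[i:]:
            w = float(similarity.loc[a, b])
            if a != b and w > 0:
                rows.append({"id_a": a, "id_b": b, "weight": w})
    pd.DataFrame(rows, columns=["id_a", "id_b", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_disease(path: str | Path) -> set[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return set(zip(df["gene_id"], df["disease_id"]))


def write_gene_disease(relations: Iterable[tuple], path: str | Path) -> None:
    pd.DataFrame(
        sorted(relations), columns=["gene_id", "disease_id"]
    ).to_csv(path, sep="\t", index=False)


# -- JSON truth -------------------------------------------------------------

def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (set, frozenset)):
            return sorted(o, key=str)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
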