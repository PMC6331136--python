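"""Candidate single-base m6A samples from peak regions, sequence and IP coverage.

MeRIP-seq peaks localize m6A to ~100-bp windows; the methylated adenosine
itself sits on a DRACH 5-mer (D=A/G/U, R=A/G, H=A/C/U).  This module scans
peak regions for DRACH centers, extracts the 101-nt window centered at the
``A`` together with the per-base IP read counts, and encodes both into the
matrices the site classifier consumes:

* ``M_s``   -- 4x101 one-hot sequence matrix (row order A, U, C, G);
* ``RC_norm`` -- log library-size-normalized IP coverage,
  ``ln(RC / RC_total * 1e8)`` per base;
* ``M_sr``  -- ``M_s @ diag(RC_norm)``, the coverage-weighted one-hot input.

All transcript coordinates are 0-based half-open; transcripts are sense-strand
RNA (``T`` is accepted and mapped to ``U``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

WINDOW = 101
HALF_WINDOW = WINDOW // 2  # 50; the center A sits at 0-based offset 50

#: one-hot row order; pinned so encodings are comparable across runs
BASE_ORDER = "AUCG"
_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}

# DRACH degenerate alphabet
_DRACH = (set("AGU"), set("AG"), set("A"), set("C"), set("ACU"))


@dataclass(frozen=True)
class PeakRegion:
    """A MeRIP-seq peak projected onto a transcript (0-based half-open)."""

    transcript_id: str
    start: int
    end: int
    gene_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid peak interval [{self.start}, {self.end}) "
                f"on {self.transcript_id}"
            )


@dataclass
class CandidateSample:
    """A DRACH-centered 101-nt candidate site with its IP coverage window."""

    transcript_id: str
    center_pos: int  # 0-based transcript coordinate of the central A
    motif: str  # the DRACH 5-mer
    sequence: str  # 101 nt over {A,C,G,U}
    rc: np.ndarray  # raw IP counts, length 101, >= 0
    rc_total: int  # IP library size
    gene_id: str = ""
    label: str = "unknown"  # positive | negative | unknown

    @property
    def site(self) -> tuple[str, int]:
        return (self.transcript_id, self.center_pos)


def clean_rna(sequence: str) -> str:
    """Uppercase and map DNA ``T`` to RNA ``U``."""
    return sequence.upper().replace("T", "U")


def scan_drach(sequence: str) -> list[int]:
    """Return 0-based positions of the central ``A`` of every DRACH match.

    ``N`` (or any non-DRACH character) never matches.  Positions are sorted
    ascending; the scan is over all 5-mers so overlapping motifs all count.
    """
    seq = clean_rna(sequence)
    hits = []
    for i in range(2, len(seq) - 2):
        if all(seq[i - 2 + k] in _DRACH[k] for k in range(5)):
            hits.append(i)
    return hits


def one_hot(sequence: str) -> np.ndarray:
    """Encode an RNA sequence as a 4 x L binary matrix (rows A, U, C, G)."""
    seq = clean_rna(sequence)
    m = np.zeros((4, len(seq)), dtype=np.float64)
    for j, base in enumerate(seq):
        try:
            m[_BASE_INDEX[base], j] = 1.0
        except KeyError:
            raise ValueError(f"non-AUCG character {base!r} at position {j}") from None
    return m


def normalize_reads(rc: np.ndarray, rc_total: int, floor: float = 1.0) -> np.ndarray:
    """Log library-size normalization of raw IP counts.

    ``RC_norm[j] = ln(max(RC[j], floor) / RC_total * 1e8)``.  The floor (a
    pseudo-count of one read) keeps the log finite at zero-coverage bases.
    """
    if rc_total <= 0:
        raise ValueError(f"RC_total must be positive, got {rc_total}")
    rc = np.asarray(rc, dtype=np.float64)
    if np.any(rc < 0):
        raise ValueError("raw read counts must be nonnegative")
    return np.log(np.maximum(rc, floor) / rc_total * 1e8)


def average_replicates(rc_norm_list: Sequence[np.ndarray]) -> np.ndarray:
    """Elementwise mean of normalized coverage vectors across replicates."""
    if len(rc_norm_list) == 0:
        raise ValueError("need at least one replicate")
    stack = np.stack([np.asarray(v, dtype=np.float64) for v in rc_norm_list])
    return stack.mean(axis=0)


def build_input(m_s: np.ndarray, rc_norm: np.ndarray) -> np.ndarray:
    """Coverage-weighted one-hot input ``M_sr = M_s @ diag(RC_norm)``.

    Column ``j`` of the result carries ``RC_norm[j]`` in the row of base ``j``.
    """
    m_s = np.asarray(m_s, dtype=np.float64)
    rc_norm = np.asarray(rc_norm, dtype=np.float64)
    if m_s.ndim != 2 or m_s.shape[0] != 4 or rc_norm.shape != (m_s.shape[1],):
        raise ValueError(
            f"shape mismatch: M_s {m_s.shape}, RC_norm {rc_norm.shape}"
        )
    return m_s * rc_norm[np.newaxis, :]


def encode_candidate(
    candidate: CandidateSample, *, sequence_only: bool = False
) -> np.ndarray:
    """Encode one candidate into the 4x101 classifier input.

    With ``sequence_only`` the coverage weights are replaced by ones, so the
    input degenerates to the plain one-hot matrix (sequence-only model).
    """
    m_s = one_hot(candidate.sequence)
    if sequence_only:
        return m_s
    rc_norm = normalize_reads(candidate.rc, candidate.rc_total)
    return build_input(m_s, rc_norm)


def encode_candidates(
    candidates: Sequence[CandidateSample], *, sequence_only: bool = False
) -> np.ndarray:
    """Stack candidate encodings into an (n, 4, 101) array."""
    return np.stack(
        [encode_candidate(c, sequence_only=sequence_only) for c in candidates]
    )


def generate_candidates(
    peaks: Iterable[PeakRegion],
    transcripts: Mapping[str, str],
    coverage: Mapping[str, np.ndarray],
    rc_total: int,
) -> list[CandidateSample]:
    """One candidate per DRACH center inside a peak.

    The 101-nt window must lie fully inside the transcript; motif centers
    closer than 50 nt to either transcript end are dropped rather than padded.
    Duplicate centers (overlapping peaks) are emitted once.  Output order is
    (transcript_id, center_pos), independent of the peak input order.
    """
    seen: set[tuple[str, int]] = set()
    out: list[CandidateSample] = []
    for peak in peaks:
        if peak.transcript_id not in transcripts:
            raise KeyError(
                f"peak references unknown transcript {peak.transcript_id!r}"
            )
        seq = clean_rna(transcripts[peak.transcript_id])
        if peak.end > len(seq):
            raise ValueError(
                f"peak [{peak.start}, {peak.end}) exceeds transcript "
                f"{peak.transcript_id!r} of length {len(seq)}"
            )
        cov = np.asarray(coverage[peak.transcript_id], dtype=np.float64)
        if cov.shape != (len(seq),):
            raise ValueError(
                f"coverage length {cov.shape[0]} != transcript length "
                f"{len(seq)} for {peak.transcript_id!r}"
            )
        # scan only within the peak; motif needs 2 nt of context either side
        lo = max(peak.start - 2, 0)
        hi = min(peak.end + 2, len(seq))
        for center in scan_drach(seq[lo:hi]):
            pos = lo + center
            if not (peak.start <= pos < peak.end):
                continue
            if pos - HALF_WINDOW < 0 or pos + HALF_WINDOW + 1 > len(seq):
                continue  # window truncated at a transcript end
            key = (peak.transcript_id, pos)
            if key in seen:
                continue
            seen.add(key)
            window = slice(pos - HALF_WINDOW, pos + HALF_WINDOW + 1)
            out.append(
                CandidateSample(
                    transcript_id=peak.transcript_id,
                    center_pos=pos,
                    motif=seq[pos - 2 : pos + 3],
                    sequence=seq[window],
                    rc=cov[window].copy(),
                    rc_total=rc_total,
                    gene_id=peak.gene_id,
                )
            )
    out.sort(key=lambda c: (c.transcript_id, c.center_pos))
    return out


def label_training(
    candidates: Sequence[CandidateSample],
    positive_sites: set[tuple[str, int]],
    exclusion_sites: set[tuple[str, int]] | None = None,
    min_distance: int = 50,
) -> list[CandidateSample]:
    """Assign training labels and drop ambiguous candidates.

    A candidate matching a known positive site is labeled positive.  A
    candidate farther than ``min_distance`` nt from every positive on its
    transcript and absent from the exclusion set is a clean negative.  All
    others (too close to a positive, or excluded by orthogonal evidence)
    are dropped.
    """
    exclusion_sites = exclusion_sites or set()
    pos_by_tx: dict[str, list[int]] = {}
    for tx, pos in positive_sites:
        pos_by_tx.setdefault(tx, []).append(pos)

    labeled: list[CandidateSample] = []
    for cand in candidates:
        if cand.site in positive_sites:
            cand.label = "positive"
            labeled.append(cand)
            continue
        if cand.site in exclusion_sites:
            continue
        nearby = pos_by_tx.get(cand.transcript_id, [])
        dist = min(
            (abs(cand.center_pos - p) for p in nearby), default=None
        )
        if dist is not None and dist <= min_distance:
            continue
        cand.label = "negative"
        labeled.append(cand)
    return labeled
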