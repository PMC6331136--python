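"""Candidate extraction and input encoding."""

import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from m6aflow.encoding import (
    PeakRegion, average_replicates, build_input, generate_candidates,
    label_training, normalize_reads, one_hot, scan_drach,
)

# independent oracle: DRACH as a regular expression with overlap lookahead
_DRACH_RE = re.compile(r"(?=([AGU][AG]AC[ACU]))")


def _scan_oracle(seq: str) -> list[int]:
    return [m.start() + 2 for m in _DRACH_RE.finditer(seq)]


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("GGACU", [2]),
        ("GGACG", []),  # G is not in H
        ("AAACAGGACU", [2, 7]),
        ("", []),
        ("NNNNNNN", []),
        ("ggacu", [2]),  # case-insensitive
        ("GGACUGGACU", [2, 7]),  # adjacent motifs both found
    ],
)
def test_scan_drach_examples(seq, expected):
    assert scan_drach(seq) == expected


@given(st.text(alphabet="ACGUN", min_size=0, max_size=80))
@settings(max_examples=200, deadline=None)
def test_scan_drach_matches_regex_oracle(seq):
    assert scan_drach(seq) == _scan_oracle(seq)


def test_one_hot_rows_and_columns():
    m = one_hot("AUCG")
    assert m.shape == (4, 4)
    # row order A, U, C, G: each base maps to its unit column
    assert np.array_equal(m, np.eye(4))
    assert np.array_equal(one_hot("A")[:, 0], [1, 0, 0, 0])
    assert np.array_equal(one_hot("G")[:, 0], [0, 0, 0, 1])
    all_a = one_hot("A" * 7)
    assert all_a[0].sum() == 7 and all_a[1:].sum() == 0
    assert np.array_equal(one_hot("T")[:, 0], [0, 1, 0, 0])  # DNA input


def test_one_hot_rejects_unknown_characters():
    with pytest.raises(ValueError, match="non-AUCG"):
        one_hot("AUNCG")


def test_normalize_reads_closed_forms():
    rc = np.full(101, 100.0)
    out = normalize_reads(rc, 10**8)
    assert out == pytest.approx(np.log(100.0), abs=1e-12)
    out = normalize_reads(np.full(101, 1e8), 10**8)
    assert out == pytest.approx(np.log(1e8), abs=1e-9)
    # zero counts are floored to one read
    assert np.array_equal(
        normalize_reads(np.zeros(101), 1000), normalize_reads(np.ones(101), 1000)
    )


def test_normalize_reads_rejects_bad_totals():
    with pytest.raises(ValueError):
        normalize_reads(np.ones(101), 0)
    with pytest.raises(ValueError):
        normalize_reads(-np.ones(101), 10)


def test_average_replicates():
    v = np.arange(101, dtype=float)
    assert np.array_equal(average_replicates([v, v]), v)
    assert np.array_equal(
        average_replicates([np.full(101, 2.0), np.full(101, 4.0)]),
        np.full(101, 3.0),
    )
    assert np.array_equal(average_replicates([v]), v)
    with pytest.raises(ValueError):
        average_replicates([])


def test_build_input_diagonal_product():
    m_s = one_hot("G" * 101)
    assert np.array_equal(build_input(m_s, np.ones(101)), m_s)
    assert build_input(m_s, np.zeros(101)).sum() == 0
    rc = np.zeros(101)
    rc[13] = 2.5
    out = build_input(m_s, rc)
    assert np.array_equal(out[:, 13], [0, 0, 0, 2.5])
    with pytest.raises(ValueError):
        build_input(m_s, np.ones(100))


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None)
def test_build_input_conserves_coverage_mass(seed):
    """Column sums of M_sr reproduce RC_norm exactly (one-hot columns)."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGU"), size=101))
    rc_norm = rng.normal(size=101)
    out = build_input(one_hot(seq), rc_norm)
    assert np.array_equal(out.sum(axis=0), rc_norm)


def _toy_transcript():
    # a 400-nt transcript with DRACH centers planted at 30, 150, 200, 260
    rng = np.random.default_rng(0)
    seq = list("".join(rng.choice(list("CG"), size=400)))  # no accidental DRACH
    for pos in (30, 150, 200, 260):
        seq[pos - 2 : pos + 3] = list("GGACU")
    return "".join(seq)


def test_generate_candidates_inside_peaks():
    tx = {"t1": _toy_transcript()}
    cov = {"t1": np.ones(400)}
    # peak spanning the three interior motifs
    cands = generate_candidates(
        [PeakRegion("t1", 120, 300)], tx, cov, rc_total=1000
    )
    assert [c.center_pos for c in cands] == [150, 200, 260]
    assert all(c.motif == "GGACU" for c in cands)
    assert all(len(c.sequence) == 101 and c.sequence[50] == "A" for c in cands)
    # every candidate's positions 48-52 match DRACH
    assert all(scan_drach(c.sequence) and 50 in scan_drach(c.sequence)
               for c in cands)


def test_generate_candidates_drops_truncated_windows():
    tx = {"t1": _toy_transcript()}
    cov = {"t1": np.ones(400)}
    # only motif center at 30 < 50 nt from the 5' end: window truncated
    cands = generate_candidates([PeakRegion("t1", 0, 60)], tx, cov, 1000)
    assert cands == []


def test_generate_candidates_order_independent_and_deduplicated():
    tx = {"t1": _toy_transcript()}
    cov = {"t1": np.arange(400, dtype=float)}
    peaks = [PeakRegion("t1", 120, 300), PeakRegion("t1", 140, 220)]
    a = generate_candidates(peaks, tx, cov, 1000)
    b = generate_candidates(peaks[::-1], tx, cov, 1000)
    assert [c.site for c in a] == [c.site for c in b]
    assert len({c.site for c in a}) == len(a)


def test_generate_candidates_unknown_transcript():
    with pytest.raises(KeyError, match="tX"):
        generate_candidates([PeakRegion("tX", 0, 10)], {}, {}, 1000)


def test_label_training_rules():
    tx = {"t1": _toy_transcript()}
    cov = {"t1": np.ones(400)}
    cands = generate_candidates([PeakRegion("t1", 120, 300)], tx, cov, 1000)
    by_pos = {c.center_pos: c for c in cands}

    labeled = label_training(cands, positive_sites={("t1", 150)})
    labels = {c.center_pos: c.label for c in labeled}
    assert labels[150] == "positive"
    # 200 is exactly 50 nt from the positive -> dropped (needs > 50)
    assert 200 not in labels
    assert labels[260] == "negative"  # 110 nt away

    # exclusion set removes an otherwise clean negative
    labeled = label_training(
        cands, positive_sites={("t1", 150)}, exclusion_sites={("t1", 260)}
    )
    assert {c.center_pos for c in labeled} == {150}


def test_fixture_candidates_are_all_drach_centered(small_training):
    for c in small_training["candidates"]:
        assert c.sequence[50] == "A"
        assert 50 in scan_drach(c.sequence)
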