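"""Alignment engine vs independent oracles; E-value analytics; validation rules."""

import math
import random
from functools import lru_cache

import pytest
from Bio import Align
from Bio.Align import substitution_matrices

from threeputr.homology import (
    BLOSUM62,
    DNA_MATRIX,
    SearchDatabase,
    SearchParams,
    evalue,
    parse_gene_name,
    search,
    sw_align,
    tabular_line,
    validate_and_annotate,
)
from threeputr.orf_finder import OrfCandidate
from threeputr.seqio import SeqRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def naive_local_score(a, b, matrix, gap_open, gap_extend):
    """Exhaustive top-down recursion over all local alignments.

    ``ext(i, j, state)`` is the best score of any (possibly empty)
    alignment continuation from (i, j); a gap of length L costs
    gap_open + L * gap_extend, charged per column with the opening cost on
    the first gap column.
    """
    n, m = len(a), len(b)

    @lru_cache(maxsize=None)
    def ext(i, j, state):
        best = 0
        if i < n and j < m:
            best = max(best, matrix.score(a[i], b[j]) + ext(i + 1, j + 1, "M"))
        if i < n:
            cost = gap_extend if state == "U" else gap_open + gap_extend
            best = max(best, -cost + ext(i + 1, j, "U"))
        if j < m:
            cost = gap_extend if state == "L" else gap_open + gap_extend
            best = max(best, -cost + ext(i, j + 1, "L"))
        return best

    return max(ext(i, j, "M") for i in range(n + 1) for j in range(m + 1))


def test_sw_align_identical_proteins_sum_of_diagonal():
    hit = sw_align("MKKV", "MKKV", BLOSUM62)
    assert hit.raw_score == 5 + 5 + 5 + 4 == 19
    assert hit.identity_pct == 100.0
    assert hit.query_span == (0, 4) and hit.subject_span == (0, 4)


def test_sw_align_no_positive_cell_is_empty():
    hit = sw_align("AAAA", "CCCC", DNA_MATRIX)
    assert hit.raw_score == 0
    assert hit.align_len == 0


def test_sw_align_rejects_alphabet_mismatch():
    with pytest.raises(ValueError, match="alphabet"):
        sw_align("ACGT", "AC!T", DNA_MATRIX)


def test_sw_align_matches_exhaustive_recursion():
    rng = random.Random(11)
    for trial in range(200):
        if trial % 2:
            mat, alpha, go, ge = BLOSUM62, AA, 11, 1
        else:
            mat, alpha, go, ge = DNA_MATRIX, "ACGT", 5, 2
        a = "".join(rng.choice(alpha) for _ in range(rng.randint(1, 12)))
        b = "".join(rng.choice(alpha) for _ in range(rng.randint(1, 12)))
        expected = naive_local_score(a, b, mat, go, ge)
        assert sw_align(a, b, mat, go, ge).raw_score == expected


def test_sw_align_matches_biopython_pairwise_aligner():
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -12  # first gap column: open 11 + extend 1
    aligner.extend_gap_score = -1
    rng = random.Random(3)
    for _ in range(25):
        a = "".join(rng.choice(AA) for _ in range(rng.randint(20, 70)))
        b = "".join(rng.choice(AA) for _ in range(rng.randint(20, 70)))
        assert sw_align(a, b, BLOSUM62, 11, 1).raw_score == int(aligner.score(a, b))


def test_sw_align_score_is_symmetric(rng):
    for _ in range(20):
        a = "".join(rng.choice(AA) for _ in range(rng.randint(5, 40)))
        b = "".join(rng.choice(AA) for _ in range(rng.randint(5, 40)))
        assert (
            sw_align(a, b, BLOSUM62).raw_score == sw_align(b, a, BLOSUM62).raw_score
        )


def test_self_alignment_identity_and_score(rng):
    for _ in range(10):
        s = "".join(rng.choice(AA) for _ in range(rng.randint(10, 60)))
        hit = sw_align(s, s, BLOSUM62)
        assert hit.raw_score == sum(BLOSUM62.score(c, c) for c in s)
        assert hit.identity_pct == 100.0


def test_evalue_closed_form_at_zero_score():
    p = SearchParams()
    _, ev = evalue(0, 100, 5000, p)
    assert math.isclose(ev, 100 * 5000 * p.k_, rel_tol=1e-12)


def test_evalue_linear_in_database_size():
    p = SearchParams()
    _, e1 = evalue(37, 200, 10_000, p)
    _, e2 = evalue(37, 200, 20_000, p)
    assert math.isclose(e2, 2 * e1, rel_tol=1e-12)


def test_evalue_strictly_decreasing_in_score():
    p = SearchParams()
    evs = [evalue(s, 150, 30_000, p)[1] for s in range(0, 120)]
    assert all(a > b for a, b in zip(evs, evs[1:]))
    bits, ev = evalue(50, 150, 30_000, p)
    assert math.isclose(bits, (p.lambda_ * 50 - math.log(p.k_)) / math.log(2))
    assert math.isclose(ev, 150 * 30_000 * 2.0 ** -bits)


def _random_protein(rng, n):
    return "".join(rng.choice(AA) for _ in range(n))


def _mutate(rng, seq, rate):
    return "".join(
        rng.choice(AA.replace(c, "")) if rng.random() < rate else c for c in seq
    )


def test_search_self_match_ranks_first():
    rng = random.Random(5)
    db = [
        SeqRecord(f"p{i}", "", _random_protein(rng, 200), "protein") for i in range(6)
    ]
    query = SeqRecord("q", "", db[3].sequence, "protein")
    hits = search(query, db, SearchParams())
    assert hits[0].subject_id == "p3"
    assert hits[0].identity_pct == 100.0
    assert hits[0].query_cov_pct == 100.0


def test_search_unrelated_random_db_yields_no_hits():
    rng = random.Random(6)
    db = [
        SeqRecord(f"p{i}", "", _random_protein(rng, 150), "protein") for i in range(20)
    ]
    query = SeqRecord("q", "", _random_protein(rng, 120), "protein")
    assert search(query, db, SearchParams()) == []


def test_seeded_search_agrees_with_full_dp_oracle():
    """Seeded/banded search reproduces exhaustive DP's top hit on homologous sets."""
    rng = random.Random(2024)
    n_compared = 0
    for _ in range(50):
        db = [
            SeqRecord(f"s{i}", "", _random_protein(rng, rng.randint(70, 120)), "protein")
            for i in range(5)
        ]
        target = rng.randrange(5)
        query = SeqRecord("q", "", _mutate(rng, db[target].sequence, 0.10), "protein")
        params = SearchParams()
        seeded = search(query, db, params)
        full = search(query, db, params, full_dp=True)
        assert full, "homologous pair must survive full-DP search"
        assert seeded, "seeded search missed a homolog with exact seeds"
        assert seeded[0].subject_id == full[0].subject_id == f"s{target}"
        assert seeded[0].raw_score == full[0].raw_score
        # the heuristic can never overshoot the exhaustive optimum
        full_by_id = {h.subject_id: h.raw_score for h in full}
        for h in seeded:
            assert h.raw_score <= full_by_id[h.subject_id]
        n_compared += 1
    assert n_compared == 50


def test_tightening_evalue_filter_never_adds_hits():
    rng = random.Random(9)
    db = [
        SeqRecord(f"s{i}", "", _random_protein(rng, 100), "protein") for i in range(4)
    ]
    query = SeqRecord("q", "", _mutate(rng, db[1].sequence, 0.3), "protein")
    loose = search(query, db, SearchParams(max_evalue=10.0, min_identity_pct=0,
                                           min_query_cov_pct=0))
    tight = search(query, db, SearchParams(max_evalue=1e-10, min_identity_pct=0,
                                           min_query_cov_pct=0))
    assert {h.subject_id for h in tight} <= {h.subject_id for h in loose}


def _candidate(aa_seq, tid="t1"):
    return OrfCandidate(
        transcript_id=tid, strand="+", frame=0, start_mrna=0,
        stop_start_mrna=3 * len(aa_seq), aa_seq=aa_seq,
    )


def test_validation_falls_back_to_shorter_orf():
    rng = random.Random(21)
    real = _random_protein(rng, 80)
    decoy = _random_protein(rng, 120)  # longer but unrelated to the db
    db = [SeqRecord("sp|Q1|REAL", "GN=geneA", real, "protein")]
    result = validate_and_annotate(
        [_candidate(decoy), _candidate(real)], db, SearchParams()
    )
    assert result is not None
    cand, hit, gene = result
    assert cand.aa_seq == real
    assert hit.subject_id == "sp|Q1|REAL"
    assert gene == "geneA"


def test_validation_returns_none_when_nothing_hits():
    rng = random.Random(22)
    db = [SeqRecord("sp|Q2|X", "", _random_protein(rng, 90), "protein")]
    result = validate_and_annotate(
        [_candidate(_random_protein(rng, 100))], db, SearchParams()
    )
    assert result is None


def test_validation_best_hit_is_lowest_evalue_paralog():
    rng = random.Random(23)
    protein = _random_protein(rng, 150)
    near = _mutate(rng, protein, 0.02)
    far = _mutate(rng, protein, 0.25)
    db = [
        SeqRecord("sp|A0|PARA2", "GN=para2", far, "protein"),
        SeqRecord("sp|A1|PARA1", "GN=para1", near, "protein"),
    ]
    result = validate_and_annotate([_candidate(protein)], db, SearchParams())
    cand, hit, gene = result
    assert hit.subject_id == "sp|A1|PARA1"
    assert gene == "para1"
    assert hit.evalue <= 1e-5


@pytest.mark.parametrize(
    "sid,desc,expected",
    [
        ("sp|P12345|ABC_HUMAN", "Some protein GN=Abc1 PE=1", "Abc1"),
        ("sp|P12345|ABC_HUMAN", "no gene token", "P12345"),
        ("plainid", "", "plainid"),
    ],
)
def test_parse_gene_name_precedence(sid, desc, expected):
    assert parse_gene_name(SeqRecord(sid, desc, "M", "protein")) == expected


def test_tabular_line_is_twelve_one_based_columns():
    rng = random.Random(30)
    db = [SeqRecord("s0", "", _random_protein(rng, 60), "protein")]
    query = SeqRecord("q", "", db[0].sequence, "protein")
    (hit,) = search(query, db, SearchParams())
    cols = tabular_line(hit).split("\t")
    assert len(cols) == 12
    assert cols[0] == "q" and cols[1] == "s0"
    assert int(cols[6]) == 1 and int(cols[7]) == 60  # 1-based inclusive span
    assert float(cols[2]) == 100.0


def test_search_requires_nonempty_db():
    with pytest.raises(ValueError, match="non-empty"):
        SearchDatabase([], BLOSUM62, 3)
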