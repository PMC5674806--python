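"""Scored local-alignment homology search with E-value statistics.

This module is the package's built-in search engine standing where a BLAST
call would sit in a classical pipeline: substitution-matrix local alignment
(Gotoh affine-gap Smith-Waterman), exact-word seeding with ungapped x-drop
extension and banded gapped refinement, and Karlin-Altschul bit-scores and
E-values. It deliberately wraps no external binary, so the whole pipeline
is self-contained and deterministic.

Three search modes:

* ``protein``     — protein query vs protein database (BLOSUM62 default);
* ``nucleotide``  — DNA vs DNA (+2/-3 match/mismatch default);
* ``translated``  — DNA query conceptually translated in up to six frames
  against a protein database; each hit records the frame and strand, and
  its query coordinates are in residues of that frame's translation.

A ``full_dp`` flag bypasses seeding and runs exhaustive Smith-Waterman per
subject; the seeded path can never exceed it, which makes it the natural
oracle in tests.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

try:  # the DP kernels are JIT-compiled when numba is available
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

from .seqio import CodonTable, SeqRecord, STANDARD_TABLE, reverse_complement, translate

SearchMode = Literal["protein", "nucleotide", "translated"]

_NEG = -(10**9)


# ---------------------------------------------------------------------------
# scoring matrices


class SubstitutionMatrix:
    """Symmetric residue-pair scoring matrix over a finite alphabet.

    Wildcards ('X' for proteins, 'N' for nucleotides) score 0 against
    everything, so ambiguous residues neither support nor penalize an
    alignment. '*' (stop in conceptual translations) is strongly penalized
    so local alignments never cross a stop.
    """

    def __init__(self, name: str, alphabet: str, scores: np.ndarray, wildcard: str):
        if scores.shape != (len(alphabet), len(alphabet)):
            raise ValueError("score matrix shape does not match alphabet")
        if not np.array_equal(scores, scores.T):
            raise ValueError("substitution matrix must be symmetric")
        self.name = name
        self.alphabet = alphabet
        self.wildcard = wildcard
        self.wildcard_index = alphabet.index(wildcard)
        self._scores = [[int(v) for v in row] for row in scores]
        self.np_scores = scores.astype(np.int64)
        # bytes translation table: ASCII -> alphabet index, unknown -> wildcard
        table = bytearray([self.wildcard_index]) * 256
        for i, ch in enumerate(alphabet):
            table[ord(ch)] = i
        self._trans = bytes(table)
        # indices that must not anchor a seed (wildcards and stops)
        self.seed_excluded = frozenset(
            alphabet.index(c) for c in (wildcard, "*") if c in alphabet
        )

    def score(self, a: str, b: str) -> int:
        return self._scores[self._index(a)][self._index(b)]

    def _index(self, ch: str) -> int:
        i = self.alphabet.find(ch)
        return self.wildcard_index if i < 0 else i

    def encode(self, seq: str, strict: bool = False) -> bytes:
        if strict:
            bad = set(seq) - set(self.alphabet)
            if bad:
                raise ValueError(
                    f"character(s) {sorted(bad)!r} outside matrix alphabet {self.name}"
                )
        return seq.encode("ascii").translate(self._trans)

    @property
    def rows(self) -> list[list[int]]:
        return self._scores

    @classmethod
    def blosum62(cls) -> "SubstitutionMatrix":
        m = substitution_matrices.load("BLOSUM62")
        alphabet = str(m.alphabet)
        scores = np.array(m, dtype=int)
        x = alphabet.index("X")
        star = alphabet.index("*")
        scores[x, :] = 0
        scores[:, x] = 0
        scores[star, :] = -4
        scores[:, star] = -4
        scores[star, star] = 1
        scores[x, star] = scores[star, x] = -4
        return cls("BLOSUM62", alphabet, scores, wildcard="X")

    @classmethod
    def nucleotide(cls, match: int = 2, mismatch: int = -3) -> "SubstitutionMatrix":
        alphabet = "ACGTN"
        scores = np.full((5, 5), mismatch, dtype=int)
        np.fill_diagonal(scores, match)
        scores[4, :] = 0
        scores[:, 4] = 0
        return cls(f"DNA{match:+d}/{mismatch:+d}", alphabet, scores, wildcard="N")


BLOSUM62 = SubstitutionMatrix.blosum62()
DNA_MATRIX = SubstitutionMatrix.nucleotide()


# ---------------------------------------------------------------------------
# parameters and hit container


@dataclass
class SearchParams:
    """Search configuration, including Karlin-Altschul statistics.

    ``lambda_`` and ``k_`` default to the published gapped parameterization
    for the default scoring systems (BLOSUM62 with gap 11/1 for proteins;
    +2/-3 with gap 5/2 for nucleotides); they are plain fields, overridable
    when a different scoring system is used. A gap of length L costs
    ``gap_open + L * gap_extend``. ``ungapped_trigger`` is the raw score an
    ungapped seed extension must reach before banded gapped DP is run for
    that subject.
    """

    gap_open: int = 11
    gap_extend: int = 1
    seed_len: int = 3
    xdrop: int = 20
    band: int = 32
    ungapped_trigger: int = 25
    lambda_: float = 0.267
    k_: float = 0.041
    max_evalue: float = 1e-5
    min_identity_pct: float = 35.0
    min_query_cov_pct: float = 50.0
    db_size_override: Optional[int] = None

    def __post_init__(self) -> None:
        if self.lambda_ <= 0 or self.k_ <= 0:
            raise ValueError("lambda_ and k_ must be positive")

    @classmethod
    def protein(cls, **over) -> "SearchParams":
        return cls(**over)

    @classmethod
    def nucleotide(cls, **over) -> "SearchParams":
        base = dict(
            gap_open=5,
            gap_extend=2,
            seed_len=11,
            lambda_=0.625,
            k_=0.41,
            min_identity_pct=80.0,
        )
        base.update(over)
        return cls(**base)

    @classmethod
    def translated(cls, **over) -> "SearchParams":
        # query coverage is meaningless for a six-frame translation of a
        # transcript with a long UTR, so it is not filtered by default
        base = dict(min_query_cov_pct=0.0)
        base.update(over)
        return cls(**base)


@dataclass
class AlignmentHit:
    """One scored local alignment between a query and a database subject.

    Spans are 0-based half-open in the respective sequences (for translated
    searches the query span is in residues of the recorded frame's
    conceptual translation). ``bitscore``/``evalue`` are populated by
    database searches; a bare :func:`sw_align` leaves them None.
    """

    query_id: str
    subject_id: str
    raw_score: int
    bitscore: Optional[float]
    evalue: Optional[float]
    identity_pct: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    query_cov_pct: float
    subject_cov_pct: float
    align_len: int
    n_ident: int
    mismatches: int
    gap_opens: int
    strand: Optional[str] = None
    frame: Optional[int] = None


def evalue(
    raw_score: int, m: int, n: int, params: SearchParams
) -> tuple[float, float]:
    """Karlin-Altschul bit-score and E-value for a raw alignment score.

    ``bitscore = (lambda * S - ln K) / ln 2`` and ``E = m * n * 2**-bitscore``
    with m the query length and n the total database residue count (or
    ``db_size_override``). At S=0 this reduces to ``E = m * n * K``.
    """
    if raw_score < 0:
        raise ValueError("raw score must be non-negative")
    bits = (params.lambda_ * raw_score - math.log(params.k_)) / math.log(2)
    ev = m * n * math.pow(2.0, -bits)
    return bits, ev


# ---------------------------------------------------------------------------
# alignment kernels


def _fill_full_py(qa, sa, smat, go: int, ge: int, pH, pE, pF):
    """Score pass of full Gotoh local DP; fills pointer matrices.

    Pointer codes: pH 0 stop, 1 diag, 2 up (gap in subject), 3 left (gap in
    query); pE/pF 1 when the gap opened from H, 0 when it extended.
    """
    n, m = len(qa), len(sa)
    gap_init = go + ge
    width = m + 1
    H_prev = [0] * width
    F_prev = [_NEG] * width
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        row_scores = smat[qa[i - 1]]
        H_cur = [0] * width
        F_cur = [_NEG] * width
        E = _NEG
        pH_i, pE_i, pF_i = pH[i], pE[i], pF[i]
        h_diag = H_prev[0]
        for j in range(1, width):
            e_open = H_cur[j - 1] - gap_init
            e_ext = E - ge
            if e_open >= e_ext:
                E, pE_i[j] = e_open, 1
            else:
                E, pE_i[j] = e_ext, 0
            f_open = H_prev[j] - gap_init
            f_ext = F_prev[j] - ge
            if f_open >= f_ext:
                F_cur[j], pF_i[j] = f_open, 1
            else:
                F_cur[j], pF_i[j] = f_ext, 0
            diag = h_diag + row_scores[sa[j - 1]]
            h_diag = H_prev[j]
            # priority: diag > up > left > stop
            h, ptr = diag, 1
            if F_cur[j] > h:
                h, ptr = F_cur[j], 2
            if E > h:
                h, ptr = E, 3
            if h <= 0:
                h, ptr = 0, 0
            H_cur[j] = h
            pH_i[j] = ptr
            if h > best:
                best, bi, bj = h, i, j
        H_prev, F_prev = H_cur, F_cur
    return best, bi, bj


def _fill_banded_py(qa, sa, smat, go: int, ge: int, lo: int, width: int, pH, pE, pF):
    """Score pass of banded Gotoh; band coordinate k = j - i - lo."""
    n, m = len(qa), len(sa)
    gap_init = go + ge
    H_prev = [_NEG] * width
    F_prev = [_NEG] * width
    for k in range(width):
        if 0 <= k + lo <= m:
            H_prev[k] = 0
    best, bi, bk = 0, 0, 0
    for i in range(1, n + 1):
        row_scores = smat[qa[i - 1]]
        H_cur = [_NEG] * width
        F_cur = [_NEG] * width
        pH_i, pE_i, pF_i = pH[i], pE[i], pF[i]
        E = _NEG
        base = i + lo
        for k in range(width):
            j = base + k
            if j < 1 or j > m:
                E = _NEG
                continue
            h_left = H_cur[k - 1] if k >= 1 else _NEG
            e_open = h_left - gap_init
            e_ext = E - ge
            if e_open >= e_ext:
                E, pE_i[k] = e_open, 1
            else:
                E, pE_i[k] = e_ext, 0
            h_up = H_prev[k + 1] if k + 1 < width else _NEG
            f_up = F_prev[k + 1] if k + 1 < width else _NEG
            f_open = h_up - gap_init
            f_ext = f_up - ge
            if f_open >= f_ext:
                F_cur[k], pF_i[k] = f_open, 1
            else:
                F_cur[k], pF_i[k] = f_ext, 0
            h_diag = H_prev[k]
            diag = (h_diag + row_scores[sa[j - 1]]) if h_diag > _NEG // 2 else _NEG
            h, ptr = diag, 1
            if F_cur[k] > h:
                h, ptr = F_cur[k], 2
            if E > h:
                h, ptr = E, 3
            if h <= 0:
                h, ptr = 0, 0
            H_cur[k] = h
            pH_i[k] = ptr
            if h > best:
                best, bi, bk = h, i, k
        H_prev, F_prev = H_cur, F_cur
    return best, bi, bk


if _HAVE_NUMBA:
    _fill_full_nb = _njit(nogil=True)(_fill_full_py)
    _fill_banded_nb = _njit(nogil=True)(_fill_banded_py)


def _traceback(qa, sa, pH, pE, pF, bi, bc, lo=None):
    """Walk pointer matrices from the best cell back to a local start.

    In the full DP the column index is the subject coordinate j; in the
    banded DP (``lo`` set) it is the band offset k with j = i + lo + k, so
    the three moves shift the column differently.
    """
    banded = lo is not None
    i, c, state = bi, bc, "H"
    align_len = n_ident = mismatches = gap_opens = 0
    while True:
        j = i + lo + c if banded else c
        if state == "H":
            ptr = pH[i][c]
            if ptr == 0:
                break
            if ptr == 1:  # diagonal: consume both residues
                align_len += 1
                if qa[i - 1] == sa[j - 1]:
                    n_ident += 1
                else:
                    mismatches += 1
                i -= 1
                if not banded:
                    c -= 1
            elif ptr == 2:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # up: consume query residue against gap
            align_len += 1
            from_h = pF[i][c]
            i -= 1
            if banded:
                c += 1
            if from_h:
                gap_opens += 1
                state = "H"
        else:  # E, left: consume subject residue against gap
            align_len += 1
            from_h = pE[i][c]
            c -= 1
            if from_h:
                gap_opens += 1
                state = "H"
    j = i + lo + c if banded else c
    return i, j, align_len, n_ident, mismatches, gap_opens


def _alloc_pointers(n_rows, width):
    if _HAVE_NUMBA:
        shape = (n_rows, width)
        return (
            np.zeros(shape, np.uint8),
            np.zeros(shape, np.uint8),
            np.zeros(shape, np.uint8),
        )
    return tuple(
        [bytearray(width) for _ in range(n_rows)] for _ in range(3)
    )


def _as_arrays(qa: bytes, sa: bytes, matrix: "SubstitutionMatrix"):
    if _HAVE_NUMBA:
        return (
            np.frombuffer(qa, dtype=np.uint8),
            np.frombuffer(sa, dtype=np.uint8),
            matrix.np_scores,
        )
    return qa, sa, matrix.rows


def _gotoh_full(qa: bytes, sa: bytes, matrix: "SubstitutionMatrix", go: int, ge: int):
    """Full Smith-Waterman with affine gaps (Gotoh) and traceback.

    Returns (score, qspan, sspan, align_len, n_ident, mismatches, gap_opens);
    score 0 means no positive-scoring local alignment exists. Traceback
    tie-break prefers diagonal over up (gap in subject) over left (gap in
    query); the best cell is the first maximum in row-major order.
    """
    n, m = len(qa), len(sa)
    pH, pE, pF = _alloc_pointers(n + 1, m + 1)
    qa_a, sa_a, smat = _as_arrays(qa, sa, matrix)
    fill = _fill_full_nb if _HAVE_NUMBA else _fill_full_py
    best, bi, bj = fill(qa_a, sa_a, smat, go, ge, pH, pE, pF)
    if best == 0:
        return 0, (0, 0), (0, 0), 0, 0, 0, 0
    qs, ss, alen, nid, mism, gaps = _traceback(qa, sa, pH, pE, pF, bi, bj)
    return int(best), (qs, bi), (ss, bj), alen, nid, mism, gaps


def _gotoh_banded(
    qa: bytes,
    sa: bytes,
    matrix: "SubstitutionMatrix",
    go: int,
    ge: int,
    center_diag: int,
    band: int,
):
    """Banded Gotoh restricted to diagonals within ``band`` of ``center_diag``.

    The diagonal of cell (i, j) is j - i. Same return contract and
    tie-breaks as :func:`_gotoh_full`.
    """
    n, m = len(qa), len(sa)
    lo = center_diag - band
    width = 2 * band + 1
    pH, pE, pF = _alloc_pointers(n + 1, width)
    qa_a, sa_a, smat = _as_arrays(qa, sa, matrix)
    fill = _fill_banded_nb if _HAVE_NUMBA else _fill_banded_py
    best, bi, bk = fill(qa_a, sa_a, smat, go, ge, lo, width, pH, pE, pF)
    if best == 0:
        return 0, (0, 0), (0, 0), 0, 0, 0, 0
    qs, ss, alen, nid, mism, gaps = _traceback(qa, sa, pH, pE, pF, bi, bk, lo=lo)
    return int(best), (qs, bi), (ss, bi + lo + bk), alen, nid, mism, gaps


def _xdrop_extend(
    qa: bytes,
    sa: bytes,
    qpos: int,
    spos: int,
    seed_len: int,
    rows: list[list[int]],
    xdrop: int,
) -> int:
    """Best ungapped extension score through a seed, with x-drop termination."""
    score = 0
    for t in range(seed_len):
        score += rows[qa[qpos + t]][sa[spos + t]]
    best = score
    # right extension
    cur = score
    i, j = qpos + seed_len, spos + seed_len
    n, m = len(qa), len(sa)
    while i < n and j < m:
        cur += rows[qa[i]][sa[j]]
        if cur > best:
            best = cur
        elif best - cur > xdrop:
            break
        i += 1
        j += 1
    right_gain = best - score
    # left extension
    best_l = cur = 0
    i, j = qpos - 1, spos - 1
    while i >= 0 and j >= 0:
        cur += rows[qa[i]][sa[j]]
        if cur > best_l:
            best_l = cur
        elif best_l - cur > xdrop:
            break
        i -= 1
        j -= 1
    return score + right_gain + best_l


# ---------------------------------------------------------------------------
# database and search


class SearchDatabase:
    """Pre-encoded subject set with an exact k-mer seed index.

    Building the index once and reusing it across queries is what makes a
    many-transcript run cheap; a plain list of records is accepted by
    :func:`search` and wrapped on the fly.
    """

    def __init__(
        self, records: Sequence[SeqRecord], matrix: SubstitutionMatrix, seed_len: int
    ):
        if not records:
            raise ValueError("search database must be non-empty")
        self.records = list(records)
        self.matrix = matrix
        self.seed_len = seed_len
        self.encoded = [matrix.encode(r.sequence) for r in self.records]
        self.total_residues = sum(len(r.sequence) for r in self.records)
        self.by_id = {r.id: r for r in self.records}
        excluded = matrix.seed_excluded
        index: dict[bytes, list[tuple[int, int]]] = {}
        for si, enc in enumerate(self.encoded):
            for p in range(len(enc) - seed_len + 1):
                kmer = enc[p : p + seed_len]
                if any(b in excluded for b in kmer):
                    continue
                index.setdefault(kmer, []).append((si, p))
        self.index = index


def sw_align(
    a: SeqRecord | str,
    b: SeqRecord | str,
    matrix: SubstitutionMatrix,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> AlignmentHit:
    """Optimal affine-gap local alignment of two sequences.

    A gap of length L costs ``gap_open + L * gap_extend``. Returns the
    maximal raw score with one optimal trace (diagonal preferred over up
    over left); a score of 0 denotes the empty alignment.
    """
    aid, aseq = (a.id, a.sequence) if isinstance(a, SeqRecord) else ("query", a)
    bid, bseq = (b.id, b.sequence) if isinstance(b, SeqRecord) else ("subject", b)
    if not aseq or not bseq:
        raise ValueError("sw_align requires non-empty sequences")
    qa = matrix.encode(aseq, strict=True)
    sa = matrix.encode(bseq, strict=True)
    score, qspan, sspan, alen, nid, mism, gaps = _gotoh_full(
        qa, sa, matrix, gap_open, gap_extend
    )
    return _make_hit(aid, bid, score, qspan, sspan, alen, nid, mism, gaps,
                     len(aseq), len(bseq))


def _make_hit(qid, sid, score, qspan, sspan, alen, nid, mism, gaps, qlen, slen,
              strand=None, frame=None) -> AlignmentHit:
    return AlignmentHit(
        query_id=qid,
        subject_id=sid,
        raw_score=score,
        bitscore=None,
        evalue=None,
        identity_pct=(100.0 * nid / alen) if alen else 0.0,
        query_span=qspan,
        subject_span=sspan,
        query_cov_pct=100.0 * (qspan[1] - qspan[0]) / qlen if qlen else 0.0,
        subject_cov_pct=100.0 * (sspan[1] - sspan[0]) / slen if slen else 0.0,
        align_len=alen,
        n_ident=nid,
        mismatches=mism,
        gap_opens=gaps,
        strand=strand,
        frame=frame,
    )


def _search_one(
    qid: str,
    qseq: str,
    db: SearchDatabase,
    params: SearchParams,
    full_dp: bool,
    strand: Optional[str],
    frame: Optional[int],
) -> list[AlignmentHit]:
    """Hits of one (possibly frame-translated) query string against db."""
    matrix = db.matrix
    rows = matrix.rows
    qa = matrix.encode(qseq)
    qlen = len(qseq)
    n_total = params.db_size_override or db.total_residues
    if full_dp:
        targets = range(len(db.records))
        aligns = {
            si: _gotoh_full(qa, db.encoded[si], matrix, params.gap_open,
                            params.gap_extend)
            for si in targets
        }
    else:
        k = params.seed_len
        excluded = matrix.seed_excluded
        per_diag: dict[tuple[int, int], tuple[int, int]] = {}
        for p in range(qlen - k + 1):
            kmer = qa[p : p + k]
            hits = db.index.get(kmer)
            if not hits:
                continue
            if any(b in excluded for b in kmer):
                continue
            for si, sp in hits:
                key = (si, sp - p)
                if key not in per_diag:
                    per_diag[key] = (p, sp)
        best_per_subject: dict[int, tuple[int, int]] = {}
        for (si, diag), (p, sp) in per_diag.items():
            ext = _xdrop_extend(qa, db.encoded[si], p, sp, k, rows, params.xdrop)
            cur = best_per_subject.get(si)
            if cur is None or ext > cur[0]:
                best_per_subject[si] = (ext, diag)
        aligns = {}
        for si, (ext, diag) in best_per_subject.items():
            if ext < params.ungapped_trigger:
                continue
            aligns[si] = _gotoh_banded(
                qa, db.encoded[si], matrix, params.gap_open, params.gap_extend,
                diag, params.band,
            )
    out: list[AlignmentHit] = []
    for si, (score, qspan, sspan, alen, nid, mism, gaps) in aligns.items():
        if score <= 0:
            continue
        rec = db.records[si]
        hit = _make_hit(
            qid, rec.id, score, qspan, sspan, alen, nid, mism, gaps,
            qlen, len(rec.sequence), strand, frame,
        )
        bits, ev = evalue(score, qlen, n_total, params)
        hit.bitscore, hit.evalue = bits, ev
        if ev > params.max_evalue:
            continue
        if hit.identity_pct < params.min_identity_pct:
            continue
        if hit.query_cov_pct < params.min_query_cov_pct:
            continue
        out.append(hit)
    return out


def search(
    query: SeqRecord,
    db: Sequence[SeqRecord] | SearchDatabase,
    params: SearchParams,
    mode: SearchMode = "protein",
    *,
    full_dp: bool = False,
    strands: Sequence[str] = ("+", "-"),
    table: CodonTable | None = None,
) -> list[AlignmentHit]:
    """Ranked homology search of one query against a subject database.

    Survivors of the E-value / identity / query-coverage filters are sorted
    by ascending E-value, then descending raw score, then subject id. In
    translated mode the query's conceptual translations over ``strands``
    are each searched and one best alignment per subject is kept.
    """
    if not isinstance(db, SearchDatabase):
        matrix = DNA_MATRIX if mode == "nucleotide" else BLOSUM62
        db = SearchDatabase(db, matrix, params.seed_len)
    if mode == "translated":
        if query.moltype != "dna":
            raise ValueError("translated search takes a DNA query")
        table = table or STANDARD_TABLE
        hits: list[AlignmentHit] = []
        for strand in strands:
            mseq = (
                query.sequence if strand == "+" else reverse_complement(query.sequence)
            )
            for frame in range(3):
                qprot = translate(mseq, frame, table)
                if not qprot:
                    continue
                hits.extend(
                    _search_one(query.id, qprot, db, params, full_dp, strand, frame)
                )
        best: dict[str, AlignmentHit] = {}
        for h in hits:
            cur = best.get(h.subject_id)
            if cur is None or h.raw_score > cur.raw_score:
                best[h.subject_id] = h
        hits = list(best.values())
    else:
        hits = _search_one(query.id, query.sequence, db, params, full_dp, None, None)
    hits.sort(key=lambda h: (h.evalue, -h.raw_score, h.subject_id))
    return hits


# ---------------------------------------------------------------------------
# validation / annotation logic


_GN_RE = re.compile(r"\bGN=(\S+)")


def parse_gene_name(subject: SeqRecord) -> str:
    """Gene name of a database subject.

    Prefers a Uniprot-style ``GN=<name>`` token in the description, then the
    second ``|``-delimited field of the id, then the full id.
    """
    m = _GN_RE.search(subject.description)
    if m:
        return m.group(1)
    if "|" in subject.id:
        parts = subject.id.split("|")
        if len(parts) >= 2 and parts[1]:
            return parts[1]
    return subject.id


def validate_and_annotate(
    candidates: Sequence,
    protein_db: Sequence[SeqRecord] | SearchDatabase,
    params: SearchParams,
) -> Optional[tuple]:
    """Homology-validate ORF candidates, longer first, and annotate.

    Searches the first candidate's protein against the database; if it has
    no surviving hit the next candidate is tried (the shorter-ORF fallback).
    Returns (candidate, best hit, gene name) or None when no candidate has a
    hit — such transcripts are excluded downstream as likely noncoding or
    spurious.
    """
    if not isinstance(protein_db, SearchDatabase):
        protein_db = SearchDatabase(protein_db, BLOSUM62, params.seed_len)
    for cand in candidates:
        q = SeqRecord(
            id=cand.header(), description="", sequence=cand.aa_seq, moltype="protein"
        )
        hits = search(q, protein_db, params, mode="protein")
        if hits:
            best = hits[0]
            gene = parse_gene_name(protein_db.by_id[best.subject_id])
            return cand, best, gene
    return None


def tabular_line(hit: AlignmentHit) -> str:
    """Render a hit as one 12-column tabular line (1-based inclusive spans)."""
    qs, qe = hit.query_span
    ss, se = hit.subject_span
    return "\t".join(
        [
            hit.query_id,
            hit.subject_id,
            f"{hit.identity_pct:.2f}",
            str(hit.align_len),
            str(hit.mismatches),
            str(hit.gap_opens),
            str(qs + 1),
            str(qe),
            str(ss + 1),
            str(se),
            f"{hit.evalue:.2e}" if hit.evalue is not None else ".",
            f"{hit.bitscore:.1f}" if hit.bitscore is not None else ".",
        ]
    )
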