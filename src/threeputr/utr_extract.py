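"""Stop-codon localization and 3'-UTR trimming.

The 3'-UTR of a transcript starts immediately after the stop codon, so the
whole extraction problem reduces to finding that codon in a strand-aware
way. Each transcript is aligned, in conceptual translation, against its own
predicted protein; the best-scoring frame and strand give the reading frame
of the coding region, and the first in-frame stop codon at or downstream of
the alignment end is the trimming anchor. Everything 5' of that stop —
any 5'-UTR, the ORF, and the stop itself — is discarded; the remaining
suffix, always reported in mRNA sense, is the predicted 3'-UTR.

Predicted UTRs are then length-filtered and optionally labeled against a
curated UTR collection; candidates without a curated match are retained as
potentially novel, never removed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

from . import homology
from .seqio import CodonTable, SeqRecord, STANDARD_TABLE, reverse_complement

DEFAULT_MIN_UTR_LEN = 20


class LocalizationError(ValueError):
    """Translated self-alignment produced no usable hit for a transcript."""


class NoStopError(ValueError):
    """No in-frame stop codon exists downstream of the alignment end."""


@dataclass
class UtrRecord:
    """One predicted 3'-UTR with its annotation provenance.

    ``stop_end_mrna`` is the 0-based exclusive end of the stop codon on the
    mRNA-sense strand; ``utr_seq`` is the mRNA-sense transcript suffix from
    that coordinate (5'->3' of the coding strand).
    """

    transcript_id: str
    gene_name: str
    best_hit_id: str
    best_hit_evalue: float
    strand: str
    frame: int
    stop_end_mrna: int
    utr_seq: str
    utrdb_match_id: Optional[str] = None
    utrdb_match_evalue: Optional[float] = None

    @property
    def utr_length(self) -> int:
        return len(self.utr_seq)


def locate_stop_by_alignment(
    transcript: SeqRecord,
    protein: SeqRecord,
    params: homology.SearchParams | None = None,
    table: CodonTable | None = None,
    strands: Sequence[str] = ("+", "-"),
) -> tuple[str, int, int]:
    """Locate the stop codon by translated alignment to the own protein.

    Returns ``(strand, frame, stop_end_mrna)``. The transcript's six-frame
    (or strand-restricted) translations are searched against the single-entry
    database holding its own predicted protein; the best frame's alignment
    end is mapped to mRNA-sense nucleotides and extended in frame to the
    first stop codon (the alignment itself can end short of the stop when
    the C-terminus diverges or is gapped).
    """
    params = params or homology.SearchParams.translated()
    table = table or STANDARD_TABLE
    hits = homology.search(
        transcript, [protein], params, mode="translated", strands=strands, table=table
    )
    if not hits:
        raise LocalizationError(
            f"{transcript.id}: no translated alignment to its own protein"
        )
    best = hits[0]
    mseq = (
        transcript.sequence
        if best.strand == "+"
        else reverse_complement(transcript.sequence)
    )
    # alignment end in frame-translation residues -> mRNA-sense nucleotides
    nt_end = best.frame + 3 * best.query_span[1]
    stops = table.stop_codons
    for p in range(nt_end, len(mseq) - 2, 3):
        if mseq[p : p + 3] in stops:
            return best.strand, best.frame, p + 3
    raise NoStopError(
        f"{transcript.id}: no in-frame stop codon downstream of alignment end"
    )


def extract_utr(
    transcript: SeqRecord,
    strand: str,
    stop_end_mrna: int,
    *,
    gene_name: str,
    best_hit_id: str,
    best_hit_evalue: float,
    frame: int,
    table: CodonTable | None = None,
) -> UtrRecord:
    """Trim everything up to and including the stop codon.

    The returned ``utr_seq`` is the mRNA-sense suffix starting at
    ``stop_end_mrna``; for a '-'-strand ORF this equals the reverse
    complement of the corresponding contig prefix. An empty suffix yields a
    length-0 record (removed later by the length filter).
    """
    table = table or STANDARD_TABLE
    mseq = (
        transcript.sequence if strand == "+" else reverse_complement(transcript.sequence)
    )
    if not 3 <= stop_end_mrna <= len(mseq):
        raise ValueError(
            f"{transcript.id}: stop_end_mrna {stop_end_mrna} out of range "
            f"for length {len(mseq)}"
        )
    if mseq[stop_end_mrna - 3 : stop_end_mrna] not in table.stop_codons:
        raise ValueError(
            f"{transcript.id}: bases before position {stop_end_mrna} are not a stop codon"
        )
    return UtrRecord(
        transcript_id=transcript.id,
        gene_name=gene_name,
        best_hit_id=best_hit_id,
        best_hit_evalue=best_hit_evalue,
        strand=strand,
        frame=frame,
        stop_end_mrna=stop_end_mrna,
        utr_seq=mseq[stop_end_mrna:],
    )


def filter_by_length(
    records: Sequence[UtrRecord], min_len: int = DEFAULT_MIN_UTR_LEN
) -> list[UtrRecord]:
    """Keep records with ``utr_length >= min_len`` (inclusive), preserving order."""
    return [r for r in records if r.utr_length >= min_len]


def annotate_against_utrdb(
    records: Sequence[UtrRecord],
    utr_db: Sequence[SeqRecord] | homology.SearchDatabase,
    params: homology.SearchParams | None = None,
) -> list[UtrRecord]:
    """Label predicted UTRs by nucleotide search against a curated collection.

    The best surviving hit's id and E-value are recorded; records without a
    hit keep an empty match but are retained — an uncharacterized candidate
    is a potential novel 3'-UTR, not a rejection.
    """
    params = params or homology.SearchParams.nucleotide()
    if not isinstance(utr_db, homology.SearchDatabase):
        utr_db = homology.SearchDatabase(utr_db, homology.DNA_MATRIX, params.seed_len)
    out: list[UtrRecord] = []
    for rec in records:
        if rec.utr_length < params.seed_len:
            out.append(replace(rec))
            continue
        q = SeqRecord(
            id=rec.transcript_id, description="", sequence=rec.utr_seq, moltype="dna"
        )
        hits = homology.search(q, utr_db, params, mode="nucleotide")
        if hits:
            out.append(
                replace(
                    rec,
                    utrdb_match_id=hits[0].subject_id,
                    utrdb_match_evalue=hits[0].evalue,
                )
            )
        else:
            out.append(replace(rec))
    return out
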