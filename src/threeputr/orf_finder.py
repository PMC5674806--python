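"""Stop-terminated ORF enumeration and orientation-aware candidate selection.

De novo assemblies contain contigs in both orientations, so by default all
six reading frames are scanned. An ORF here is a maximal stop-to-stop (or
sequence-start-to-stop) run of codons — no initiator ATG is required, since
assembled transcripts are frequently 5'-truncated — and only runs that
actually terminate in a stop codon are emitted: without a stop there is no
3'-UTR boundary to locate. Runs that reach the 3' end unterminated are
dropped.

Coordinates of minus-strand candidates are expressed on the reverse
complement of the contig, i.e. on the mRNA-sense strand, like everything
else in the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Literal

from .seqio import CodonTable, SeqRecord, STANDARD_TABLE, reverse_complement

StrandMode = Literal["unstranded", "forward", "reverse"]

DEFAULT_MIN_AA = 50

_STRAND_ORDER = {"+": 0, "-": 1}


@dataclass(frozen=True)
class OrfCandidate:
    """A stop-terminated reading-frame interval on the mRNA-sense strand.

    ORF codons occupy ``[start_mrna, stop_start_mrna)``; the stop codon
    occupies the three bases starting at ``stop_start_mrna``.
    """

    transcript_id: str
    strand: str  # '+' or '-': '-' means the ORF lies on the contig's reverse complement
    frame: int  # offset on the mRNA-sense strand, in {0, 1, 2}
    start_mrna: int
    stop_start_mrna: int
    aa_seq: str

    @property
    def length_aa(self) -> int:
        return len(self.aa_seq)

    def __post_init__(self) -> None:
        if self.stop_start_mrna - self.start_mrna != 3 * len(self.aa_seq):
            raise ValueError("ORF span does not match 3 * length_aa")
        if self.start_mrna % 3 != self.frame:
            raise ValueError("start_mrna is not in the stated frame")
        if "*" in self.aa_seq:
            raise ValueError("aa_seq must not contain stops")

    def header(self) -> str:
        """FASTA id for intermediate files: transcriptID|strand|frame|start-stopstart."""
        return (
            f"{self.transcript_id}|{self.strand}|{self.frame}"
            f"|{self.start_mrna}-{self.stop_start_mrna}"
        )


def _iter_runs(
    mseq: str, frame: int, table: CodonTable
) -> Iterator[tuple[int, int | None, str]]:
    """Yield maximal inter-stop runs in one frame of one mRNA-sense sequence.

    Yields (start, stop_start or None, aa_seq); stop_start is None for the
    trailing run that reaches the 3' end without a stop codon. Only exact
    unambiguous TAA/TAG/TGA terminate a run.
    """
    stops = table.stop_codons
    run_start = frame
    residues: list[str] = []
    for i in range(frame, len(mseq) - 2, 3):
        codon = mseq[i : i + 3]
        if codon in stops:
            yield run_start, i, "".join(residues)
            run_start = i + 3
            residues = []
        else:
            residues.append(table.translate_codon(codon))
    if residues:
        yield run_start, None, "".join(residues)


def _strands_for_mode(mode: StrandMode) -> tuple[str, ...]:
    if mode == "unstranded":
        return ("+", "-")
    if mode == "forward":
        return ("+",)
    if mode == "reverse":
        return ("-",)
    raise ValueError(f"unknown strand mode {mode!r}")


def enumerate_orfs(
    transcript: SeqRecord,
    table: CodonTable | None = None,
    min_aa: int = DEFAULT_MIN_AA,
    mode: StrandMode = "unstranded",
    require_start_codon: bool = False,
) -> list[OrfCandidate]:
    """Enumerate stop-terminated ORFs of >= ``min_aa`` residues.

    ``mode`` selects the orientations to scan: all six frames when
    unstranded, three when the library preserves strand. With
    ``require_start_codon`` each run is trimmed to its first ATG before
    applying the length threshold.
    """
    if transcript.moltype != "dna":
        raise ValueError("ORF enumeration requires a DNA transcript")
    table = table or STANDARD_TABLE
    out: list[OrfCandidate] = []
    for strand in _strands_for_mode(mode):
        mseq = transcript.sequence if strand == "+" else reverse_complement(
            transcript.sequence
        )
        for frame in range(3):
            for start, stop_start, aa in _iter_runs(mseq, frame, table):
                if stop_start is None:
                    continue
                if require_start_codon:
                    # trim to the first ATG codon inside the run
                    atg = next(
                        (
                            k
                            for k in range(start, stop_start, 3)
                            if mseq[k : k + 3] == "ATG"
                        ),
                        None,
                    )
                    if atg is None:
                        continue
                    aa = aa[(atg - start) // 3 :]
                    start = atg
                if len(aa) < min_aa:
                    continue
                out.append(
                    OrfCandidate(
                        transcript_id=transcript.id,
                        strand=strand,
                        frame=frame,
                        start_mrna=start,
                        stop_start_mrna=stop_start,
                        aa_seq=aa,
                    )
                )
    return out


def has_open_ended_run(
    transcript: SeqRecord,
    table: CodonTable | None = None,
    min_aa: int = DEFAULT_MIN_AA,
    mode: StrandMode = "unstranded",
) -> bool:
    """True if some frame holds a run >= ``min_aa`` that never reaches a stop.

    Distinguishes transcripts dropped for lacking a stop codon (truncated
    assemblies) from transcripts with no ORF potential at all.
    """
    table = table or STANDARD_TABLE
    for strand in _strands_for_mode(mode):
        mseq = transcript.sequence if strand == "+" else reverse_complement(
            transcript.sequence
        )
        for frame in range(3):
            for _start, stop_start, aa in _iter_runs(mseq, frame, table):
                if stop_start is None and len(aa) >= min_aa:
                    return True
    return False


def _candidate_sort_key(c: OrfCandidate) -> tuple:
    # longest first; ties broken by lower frame, then smaller start
    return (-c.length_aa, c.frame, c.start_mrna)


def select_candidates(
    orfs: list[OrfCandidate], mode: StrandMode = "unstranded"
) -> list[OrfCandidate]:
    """Pick the longest ORF per orientation, ordered longest-first.

    Unstranded mode returns at most two candidates (one per strand), sorted
    by decreasing length with '+' preferred on an exact length tie; stranded
    modes return the single longest candidate on the allowed strand. The
    homology stage validates the first and falls back to the second.
    """
    if not orfs:
        return []
    ids = {c.transcript_id for c in orfs}
    if len(ids) != 1:
        raise ValueError(f"candidates span multiple transcripts: {sorted(ids)}")
    allowed = _strands_for_mode(mode)
    best: dict[str, OrfCandidate] = {}
    for c in orfs:
        if c.strand not in allowed:
            continue
        cur = best.get(c.strand)
        if cur is None or _candidate_sort_key(c) < _candidate_sort_key(cur):
            best[c.strand] = c
    return sorted(
        best.values(), key=lambda c: (-c.length_aa, _STRAND_ORDER[c.strand])
    )
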