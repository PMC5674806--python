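"""FASTA input/output, genetic-code translation, and coordinate conventions.

Conventions shared by every other module:

* Coordinates are 0-based, half-open, and expressed on the mRNA-sense strand
  (the strand carrying the coding sequence 5'->3'). Contig-strand coordinates
  are derived where needed, never stored.
* Sequences are uppercase after parsing; soft-masking case is discarded.
* DNA uses the IUPAC alphabet (ACGT plus ambiguity codes and N); proteins use
  the 20 standard residues plus X (unknown) and '*' (stop, only in conceptual
  translations, never in ORF products).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio.Data import CodonTable as _BioCodonTable
from Bio.SeqIO.FastaIO import SimpleFastaParser

Moltype = Literal["dna", "protein"]

#: IUPAC DNA alphabet (unambiguous bases, two/three/four-fold codes, N).
DNA_ALPHABET = frozenset("ACGTRYSWKMBDHVN")
#: Protein alphabet: 20 residues, ambiguity codes B/Z/J, rare U/O, X, stop.
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" "BZJUO" "X*")

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN",
    "TGCAYRSWMKVHDBN",
)

#: Expansion of each IUPAC DNA code into the unambiguous bases it denotes.
IUPAC_EXPAND = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


class FastaParseError(ValueError):
    """Raised when a FASTA file violates the input contract."""


@dataclass
class SeqRecord:
    """An identified sequence with optional free-text description.

    ``id`` is the first whitespace-delimited token of the FASTA header;
    ``description`` is the remainder (possibly empty). ``sequence`` is
    uppercase over the declared ``moltype`` alphabet.
    """

    id: str
    description: str
    sequence: str
    moltype: Moltype = "dna"

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CodonTable:
    """Total mapping of the 64 unambiguous codons to single-letter symbols.

    Stops map to '*'. The default is the standard genetic code; alternative
    tables can be loaded from a two-column text file (codon, amino acid).
    """

    codon_to_aa: dict[str, str]
    stop_codons: frozenset[str]
    _ambig_cache: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError(
                f"codon table must map all 64 codons, got {len(self.codon_to_aa)}"
            )

    def translate_codon(self, codon: str) -> str:
        """Translate one codon, applying the ambiguity rule.

        A codon containing ambiguity codes renders 'X' unless every
        expansion yields the same amino acid (e.g. GCN -> A). Expansions
        that include a stop never collapse to '*': asserting a stop
        requires an exact TAA/TAG/TGA.
        """
        aa = self.codon_to_aa.get(codon)
        if aa is not None:
            return aa
        cached = self._ambig_cache.get(codon)
        if cached is not None:
            return cached
        try:
            expansions = [IUPAC_EXPAND[b] for b in codon]
        except KeyError as exc:
            raise ValueError(f"invalid base {exc.args[0]!r} in codon {codon!r}") from None
        symbols = {
            self.codon_to_aa["".join(bases)]
            for bases in itertools.product(*expansions)
        }
        out = symbols.pop() if len(symbols) == 1 and "*" not in symbols else "X"
        if out == "*":  # unreachable given the pop guard, kept defensive
            out = "X"
        self._ambig_cache[codon] = out
        return out

    @classmethod
    def standard(cls) -> "CodonTable":
        table = _BioCodonTable.unambiguous_dna_by_id[1]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = "*"
        return cls(codon_to_aa=mapping, stop_codons=frozenset(table.stop_codons))

    @classmethod
    def from_file(cls, path: str | Path) -> "CodonTable":
        """Load a table from whitespace-separated (codon, aa) lines."""
        mapping: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2 or len(parts[0]) != 3 or len(parts[1]) != 1:
                raise ValueError(f"{path}:{lineno}: expected 'CODON AA', got {line!r}")
            mapping[parts[0].upper()] = parts[1].upper()
        stops = frozenset(c for c, aa in mapping.items() if aa == "*")
        return cls(codon_to_aa=mapping, stop_codons=stops)


STANDARD_TABLE = CodonTable.standard()


def _validate_alphabet(record: SeqRecord) -> None:
    alphabet = DNA_ALPHABET if record.moltype == "dna" else PROTEIN_ALPHABET
    bad = set(record.sequence) - alphabet
    if bad:
        pos = min(record.sequence.index(c) for c in bad)
        raise FastaParseError(
            f"record {record.id!r}: illegal {record.moltype} character "
            f"{record.sequence[pos]!r} at sequence position {pos}"
        )


def read_fasta(path: str | Path, moltype: Moltype = "dna") -> list[SeqRecord]:
    """Parse a FASTA file into an ordered list of :class:`SeqRecord`.

    Sequences are uppercased and whitespace-stripped. Duplicate ids, empty
    sequences, empty files, and characters outside the declared alphabet
    raise :class:`FastaParseError`.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            parts = header.split(None, 1)
            if not parts:
                raise FastaParseError(f"{path}: record with empty header")
            rid = parts[0]
            desc = parts[1].strip() if len(parts) > 1 else ""
            if rid in seen:
                raise FastaParseError(f"{path}: duplicate record id {rid!r}")
            seen.add(rid)
            sequence = "".join(seq.split()).upper()
            if not sequence:
                raise FastaParseError(f"{path}: record {rid!r} has an empty sequence")
            record = SeqRecord(id=rid, description=desc, sequence=sequence, moltype=moltype)
            _validate_alphabet(record)
            records.append(record)
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(
    records: Iterable[SeqRecord], path: str | Path, width: int = 60
) -> None:
    """Write records as FASTA with sequence lines wrapped at ``width`` columns.

    An empty collection writes an empty file.
    """
    if width < 1:
        raise ValueError("width must be positive")
    with open(path, "w") as handle:
        for rec in records:
            header = f">{rec.id} {rec.description}" if rec.description else f">{rec.id}"
            handle.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string; ambiguity codes follow IUPAC."""
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"non-DNA character(s) {sorted(bad)!r} in sequence")
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str, offset: int = 0, table: CodonTable | None = None) -> str:
    """Conceptual translation of ``seq`` starting at frame ``offset``.

    One symbol per complete codon; the trailing partial codon is dropped.
    Exact stop codons render '*'; ambiguity codons follow
    :meth:`CodonTable.translate_codon`. A sequence shorter than one codon
    at the offset yields the empty string.
    """
    if offset not in (0, 1, 2):
        raise ValueError(f"offset must be 0, 1 or 2, got {offset}")
    table = table or STANDARD_TABLE
    return "".join(
        table.translate_codon(seq[i : i + 3]) for i in range(offset, len(seq) - 2, 3)
    )
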