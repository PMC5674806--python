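"""Ground-truth synthetic transcriptomes for exercising the whole pipeline.

Each simulated gene is an mRNA with the canonical 5'UTR + ATG-initiated CDS
+ stop codon + 3'UTR architecture, emitted as a contig in either
orientation (de novo assemblers produce both). Alongside the well-formed
genes the generator plants the failure modes the pipeline must reject:
noncoding decoys (dinucleotide-preserving shuffles with no
homology-supported ORF), stop-less truncated transcripts, and genes whose
3'UTR falls below the length filter. The protein database holds one copy of
each coding gene's protein, diverged by a configurable per-residue
substitution rate to emulate a cross-species reference such as Uniprot; a
configurable fraction of the true UTRs forms a curated-UTR database so the
characterized/uncharacterized split is exercised too.

The truth table records, per transcript, the exact expected 3'-UTR
sequence, stop coordinate, gene name, and expected pipeline outcome under
the default thresholds, which makes closed-loop recall/precision scoring a
pure table comparison.
"""

from __future__ import annotations

import math
import random
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from . import homology, orf_finder
from .seqio import SeqRecord, STANDARD_TABLE, reverse_complement, write_fasta
from .utr_extract import DEFAULT_MIN_UTR_LEN

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# amino acid -> synonymous codons, standard code
_CODONS_BY_AA: dict[str, list[str]] = defaultdict(list)
for _codon, _aa in STANDARD_TABLE.codon_to_aa.items():
    if _aa != "*":
        _CODONS_BY_AA[_aa].append(_codon)
for _lst in _CODONS_BY_AA.values():
    _lst.sort()


@dataclass
class GenParams:
    """Generation parameters; the defaults define the study conditions.

    3'UTR lengths are log-normal (median ~400 nt, clipped to [1, 5000]),
    loosely matching vertebrate mRNA annotations; UTR composition is AT-rich
    (55%). ``db_divergence`` is the per-residue substitution rate applied to
    the database copy of each protein.
    """

    frac_normal: float = 0.70
    frac_decoy: float = 0.15
    frac_truncated: float = 0.10
    frac_short_utr: float = 0.05
    utr3_median: float = 400.0
    utr3_sigma: float = 0.7
    utr3_max: int = 5000
    utr5_min: int = 20
    utr5_max: int = 150
    cds_aa_min: int = 100
    cds_aa_max: int = 400
    at_frac: float = 0.55
    orientation_minus_frac: float = 0.5
    db_divergence: float = 0.05
    utrdb_fraction: float = 0.5
    min_aa: int = orf_finder.DEFAULT_MIN_AA
    min_utr_len: int = DEFAULT_MIN_UTR_LEN

    def validate(self) -> None:
        total = self.frac_normal + self.frac_decoy + self.frac_truncated + self.frac_short_utr
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"category fractions must sum to 1, got {total}")
        for f in (self.frac_normal, self.frac_decoy, self.frac_truncated,
                  self.frac_short_utr, self.db_divergence, self.utrdb_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions and rates must lie in [0, 1]")


@dataclass
class SyntheticGene:
    """Ground-truth architecture of one simulated transcript."""

    gene_id: str
    transcript_id: str
    category: str  # normal | decoy_noncoding | truncated_no_stop | short_utr
    contig_orientation: str  # '+' or '-'
    protein_true: str  # empty for decoys
    utr5_len: int
    cds_len: int  # coding codons only (multiple of 3), excludes the stop
    utr3_len: int
    transcript_sense: str  # mRNA-sense sequence
    contig_seq: str  # as written to the transcripts FASTA
    utr3_seq: str
    expected_outcome: str  # 'emitted' or 'dropped:<reason>'

    @property
    def stop_end_mrna(self) -> Optional[int]:
        if self.category in ("normal", "short_utr"):
            return self.utr5_len + self.cds_len + 3
        return None


@dataclass
class SimulationResult:
    """In-memory fixture: sequence sets plus the ground-truth table."""

    genes: list[SyntheticGene]
    transcripts: list[SeqRecord]
    proteins: list[SeqRecord]
    utrdb: list[SeqRecord]
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.transcripts, outdir / "transcripts.fasta")
        write_fasta(self.proteins, outdir / "proteins.fasta")
        write_fasta(self.utrdb, outdir / "utrdb.fasta")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def _random_dna(rng: random.Random, length: int, at_frac: float) -> str:
    at = at_frac / 2.0
    gc = (1.0 - at_frac) / 2.0
    return "".join(
        rng.choices("ATCG", weights=(at, at, gc, gc), k=length)
    )


def _random_protein(rng: random.Random, length_aa: int) -> str:
    return "M" + "".join(rng.choices(AA20, k=length_aa - 1))


def _reverse_translate(rng: random.Random, protein: str) -> str:
    """Back-translate with uniform synonymous codon choice (seeded)."""
    return "".join(rng.choice(_CODONS_BY_AA[aa]) for aa in protein)


def _mutate_protein(rng: random.Random, protein: str, rate: float) -> str:
    if rate <= 0:
        return protein
    out = []
    for aa in protein:
        if rng.random() < rate:
            alt = rng.choice(AA20)
            while alt == aa:
                alt = rng.choice(AA20)
            out.append(alt)
        else:
            out.append(aa)
    return "".join(out)


def dinucleotide_shuffle(seq: str, rng: random.Random) -> str:
    """Shuffle preserving exact dinucleotide counts (Altschul-Erikson).

    Builds the dinucleotide edge multigraph, fixes a random last-edge tree
    oriented toward the terminal base so an Eulerian walk exists, shuffles
    the remaining edges, and walks the graph.
    """
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    first, last = seq[0], seq[-1]
    vertices = sorted(edges.keys() | set(seq))

    def tree_reaches_last(last_edges: dict[str, str]) -> bool:
        for v in vertices:
            if v == last:
                continue
            seen = set()
            while v != last:
                if v in seen or v not in last_edges:
                    return False
                seen.add(v)
                v = last_edges[v]
        return True

    for _attempt in range(200):
        last_edges = {
            v: rng.choice(edges[v]) for v in vertices if v != last and edges[v]
        }
        if all(v == last or not edges[v] or v in last_edges for v in vertices) and \
                tree_reaches_last(last_edges):
            break
    else:  # pragma: no cover - practically unreachable for DNA
        raise RuntimeError("dinucleotide shuffle failed to find an Eulerian ordering")

    adj: dict[str, list[str]] = {}
    for v in vertices:
        lst = list(edges[v])
        reserved = last_edges.get(v)
        if reserved is not None:
            lst.remove(reserved)
        rng.shuffle(lst)
        if reserved is not None:
            lst.append(reserved)
        adj[v] = lst
    out = [first]
    ptr: dict[str, int] = {v: 0 for v in vertices}
    v = first
    for _ in range(len(seq) - 1):
        nxt = adj[v][ptr[v]]
        ptr[v] += 1
        out.append(nxt)
        v = nxt
    return "".join(out)


def _category_counts(n: int, params: GenParams) -> dict[str, int]:
    """Largest-remainder apportionment of n genes to the four categories."""
    fracs = {
        "normal": params.frac_normal,
        "decoy_noncoding": params.frac_decoy,
        "truncated_no_stop": params.frac_truncated,
        "short_utr": params.frac_short_utr,
    }
    counts = {k: int(n * f) for k, f in fracs.items()}
    remainders = sorted(
        fracs, key=lambda k: (-(n * fracs[k] - counts[k]), k)
    )
    i = 0
    while sum(counts.values()) < n:
        counts[remainders[i % len(remainders)]] += 1
        i += 1
    return counts


def _true_candidate_selected(
    contig: SeqRecord, sense_strand: str, stop_start: int, min_aa: int
) -> bool:
    """Does longest-per-strand selection retain the true CDS run?"""
    orfs = orf_finder.enumerate_orfs(contig, min_aa=min_aa, mode="unstranded")
    selected = orf_finder.select_candidates(orfs, mode="unstranded")
    return any(
        c.strand == sense_strand and c.stop_start_mrna == stop_start
        for c in selected
    )


def _dropped_reason(contig: SeqRecord, min_aa: int) -> str:
    """Expected drop reason for a transcript with no database homolog."""
    orfs = orf_finder.enumerate_orfs(contig, min_aa=min_aa, mode="unstranded")
    if orfs:
        return "dropped:NO_HIT"
    if orf_finder.has_open_ended_run(contig, min_aa=min_aa, mode="unstranded"):
        return "dropped:NO_STOP"
    return "dropped:NO_ORF"


def generate_transcriptome(
    n_genes: int, seed: int, params: GenParams | None = None
) -> SimulationResult:
    """Generate a seeded ground-truth transcriptome fixture.

    Deterministic for a given (n_genes, seed, params). Coding-gene UTR
    sequences are resampled until the true CDS run is the one that
    longest-per-strand selection retains, so the truth table's expected
    outcomes hold by construction; decoys are reshuffled until they have no
    homology-supported ORF against the generated protein database.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    params = params or GenParams()
    params.validate()
    rng = random.Random(seed)
    counts = _category_counts(n_genes, params)
    categories = [cat for cat, c in counts.items() for _ in range(c)]
    rng.shuffle(categories)

    width = max(4, len(str(n_genes)))
    genes: list[SyntheticGene] = []
    protein_records: list[SeqRecord] = []
    validation_params = homology.SearchParams.protein()

    # pass 1: coding genes (normal / short_utr / truncated), which define the db
    for idx, category in enumerate(categories):
        gene_id = f"g{idx + 1:0{width}d}"
        transcript_id = f"t{idx + 1:0{width}d}"
        orientation = "-" if rng.random() < params.orientation_minus_frac else "+"
        if category == "decoy_noncoding":
            genes.append(
                SyntheticGene(
                    gene_id, transcript_id, category, orientation, "",
                    0, 0, 0, "", "", "", "pending",
                )
            )
            continue
        cds_aa = rng.randint(params.cds_aa_min, params.cds_aa_max)
        protein = _random_protein(rng, cds_aa)
        cds = _reverse_translate(rng, protein)
        utr5_len = rng.randint(params.utr5_min, params.utr5_max)
        if category == "short_utr":
            utr3_len = rng.randint(0, max(0, params.min_utr_len - 1))
        elif category == "truncated_no_stop":
            utr3_len = 0
        else:
            utr3_len = max(
                1,
                min(
                    params.utr3_max,
                    int(round(rng.lognormvariate(math.log(params.utr3_median),
                                                 params.utr3_sigma))),
                ),
            )
        stop = rng.choice(sorted(STANDARD_TABLE.stop_codons))
        for _try in range(60):
            utr5 = _random_dna(rng, utr5_len, params.at_frac)
            utr3 = _random_dna(rng, utr3_len, params.at_frac)
            if category == "truncated_no_stop":
                sense = utr5 + cds
            else:
                sense = utr5 + cds + stop + utr3
            contig_seq = sense if orientation == "+" else reverse_complement(sense)
            contig = SeqRecord(transcript_id, "", contig_seq, "dna")
            sense_strand = "+" if orientation == "+" else "-"
            if category == "truncated_no_stop":
                break
            if _true_candidate_selected(
                contig, sense_strand, utr5_len + len(cds), params.min_aa
            ):
                break
        else:
            raise RuntimeError(
                f"{gene_id}: could not realize a transcript whose true ORF wins selection"
            )
        if category == "truncated_no_stop":
            outcome = "pending"  # reason depends on the antisense ORF content
        elif utr3_len >= params.min_utr_len:
            outcome = "emitted"
        else:
            outcome = "dropped:UTR_TOO_SHORT"
        genes.append(
            SyntheticGene(
                gene_id, transcript_id, category, orientation, protein,
                utr5_len, len(cds), utr3_len, sense, contig_seq, utr3, outcome,
            )
        )
        db_protein = _mutate_protein(rng, protein, params.db_divergence)
        protein_records.append(
            SeqRecord(
                id=f"sp|P{idx + 1:05d}|{gene_id.upper()}_SYN",
                description=f"synthetic protein GN={gene_id}",
                sequence=db_protein,
                moltype="protein",
            )
        )

    protein_db = homology.SearchDatabase(
        protein_records, homology.BLOSUM62, validation_params.seed_len
    )

    # pass 2: decoys (need the db for the no-significant-ORF invariant)
    # and deferred expected outcomes
    for gene in genes:
        if gene.category == "truncated_no_stop":
            contig = SeqRecord(gene.transcript_id, "", gene.contig_seq, "dna")
            gene.expected_outcome = _dropped_reason(contig, params.min_aa)
            continue
        if gene.category != "decoy_noncoding":
            continue
        total_len = (
            rng.randint(params.utr5_min, params.utr5_max)
            + 3 * rng.randint(params.cds_aa_min, params.cds_aa_max)
            + 3
            + max(1, min(params.utr3_max,
                         int(round(rng.lognormvariate(math.log(params.utr3_median),
                                                      params.utr3_sigma)))))
        )
        donor = _random_dna(rng, total_len, 0.5)
        for _try in range(60):
            shuffled = dinucleotide_shuffle(donor, rng)
            contig = SeqRecord(gene.transcript_id, "", shuffled, "dna")
            orfs = orf_finder.enumerate_orfs(
                contig, min_aa=params.min_aa, mode="unstranded"
            )
            candidates = orf_finder.select_candidates(orfs, mode="unstranded")
            if homology.validate_and_annotate(
                candidates, protein_db, validation_params
            ) is None:
                break
        else:
            raise RuntimeError(f"{gene.gene_id}: decoy keeps hitting the protein db")
        gene.transcript_sense = shuffled
        gene.contig_seq = shuffled
        gene.expected_outcome = _dropped_reason(contig, params.min_aa)

    transcripts = [
        SeqRecord(g.transcript_id, f"category={g.category}", g.contig_seq, "dna")
        for g in genes
    ]
    emitted_utrs = [g for g in genes if g.expected_outcome == "emitted"]
    n_db = int(round(params.utrdb_fraction * len(emitted_utrs)))
    utrdb = [
        SeqRecord(f"U_{g.gene_id}", f"curated 3'UTR of {g.gene_id}", g.utr3_seq, "dna")
        for g in rng.sample(emitted_utrs, n_db)
    ]
    utrdb.sort(key=lambda r: r.id)

    truth = pd.DataFrame(
        {
            "transcript_id": [g.transcript_id for g in genes],
            "gene_id": [g.gene_id for g in genes],
            "category": [g.category for g in genes],
            "contig_orientation": [g.contig_orientation for g in genes],
            "utr5_len": [g.utr5_len for g in genes],
            "cds_len": [g.cds_len for g in genes],
            "utr3_len": [g.utr3_len for g in genes],
            "expected_gene_name": [
                g.gene_id if g.category != "decoy_noncoding" else "." for g in genes
            ],
            "expected_stop_end_mrna": [
                g.stop_end_mrna if g.stop_end_mrna is not None else "." for g in genes
            ],
            "expected_utr_seq": [g.utr3_seq if g.utr3_seq else "." for g in genes],
            "expected_outcome": [g.expected_outcome for g in genes],
        }
    )
    return SimulationResult(genes, transcripts, protein_records, utrdb, truth)


def _read_utr_fasta(path: str | Path) -> dict[str, str]:
    from Bio.SeqIO.FastaIO import SimpleFastaParser

    out: dict[str, str] = {}
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            out[header.split(None, 1)[0]] = "".join(seq.split()).upper()
    return out


def evaluate(
    annotation_path: str | Path,
    utr_fasta_path: str | Path,
    truth_path: str | Path,
) -> dict[str, float]:
    """Score a pipeline run against the ground truth.

    Reports exact-sequence recall among transcripts expected to be emitted,
    precision (fraction of emitted records whose truth outcome is
    'emitted'), gene-name annotation accuracy, and the mean absolute
    stop-coordinate offset over emitted records with a defined truth stop.
    """
    truth = pd.read_csv(truth_path, sep="\t", dtype=str, na_filter=False)
    truth = truth.set_index("transcript_id")
    pred = pd.read_csv(annotation_path, sep="\t", dtype=str, na_filter=False)
    utr_seqs = _read_utr_fasta(utr_fasta_path)

    unknown = set(pred["transcript_id"]) - set(truth.index)
    if unknown:
        raise ValueError(f"predictions for unknown transcript ids: {sorted(unknown)}")

    expected_emitted = truth[truth["expected_outcome"] == "emitted"]
    n_expected = len(expected_emitted)
    n_pred = len(pred)

    n_exact = 0
    n_true_pos = 0
    n_gene_ok = 0
    offsets: list[float] = []
    for _, row in pred.iterrows():
        tid = row["transcript_id"]
        trow = truth.loc[tid]
        if trow["expected_outcome"] == "emitted":
            n_true_pos += 1
            if utr_seqs.get(tid, "") == trow["expected_utr_seq"]:
                n_exact += 1
            if row["gene_name"] == trow["expected_gene_name"]:
                n_gene_ok += 1
        if trow["expected_stop_end_mrna"] != ".":
            offsets.append(
                abs(int(row["stop_end_mrna"]) - int(trow["expected_stop_end_mrna"]))
            )
    return {
        "n_expected_emitted": float(n_expected),
        "n_predicted": float(n_pred),
        "recall_exact": n_exact / n_expected if n_expected else 1.0,
        "precision": n_true_pos / n_pred if n_pred else 1.0,
        "gene_name_accuracy": n_gene_ok / n_true_pos if n_true_pos else 1.0,
        "stop_mae": sum(offsets) / len(offsets) if offsets else 0.0,
        "n_false_category_emitted": float(n_pred - n_true_pos),
    }
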