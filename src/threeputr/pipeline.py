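"""End-to-end orchestration: ORF prediction -> validation -> UTR extraction.

Transcripts are independent work units processed in input order; the run is
deterministic given identical inputs and configuration. Every transcript
ends up either in the annotation sheet or in the drop log with a
machine-parsable reason code (NO_ORF, NO_STOP, NO_HIT, LOCALIZATION_FAILED,
UTR_TOO_SHORT), and the per-stage counts in the run summary reconcile
exactly with those reasons.

The stop-codon coordinate is computed twice, by direct ORF enumeration and
by translated self-alignment; when the two routes disagree the ORF
coordinate wins and the disagreement is counted in the summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import homology, orf_finder, utr_extract
from .seqio import CodonTable, SeqRecord, STANDARD_TABLE, read_fasta, write_fasta

DROP_REASONS = ("NO_ORF", "NO_STOP", "NO_HIT", "LOCALIZATION_FAILED", "UTR_TOO_SHORT")

ANNOTATION_COLUMNS = (
    "transcript_id",
    "gene_name",
    "best_hit_id",
    "best_hit_evalue",
    "strand",
    "frame",
    "stop_end_mrna",
    "utr_length",
    "utrdb_match_id",
    "utrdb_match_evalue",
)


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """Everything a full run needs; mirrors the CLI flags.

    ``threads`` is accepted for interface compatibility but transcripts are
    processed sequentially in input order, which satisfies the order-stable
    output contract by construction.
    """

    transcripts_path: str
    protein_db_path: str
    output_dir: str
    utr_db_path: Optional[str] = None
    strand_mode: orf_finder.StrandMode = "unstranded"
    min_aa: int = orf_finder.DEFAULT_MIN_AA
    min_utr_len: int = utr_extract.DEFAULT_MIN_UTR_LEN
    protein_params: homology.SearchParams = field(
        default_factory=homology.SearchParams.protein
    )
    translated_params: homology.SearchParams = field(
        default_factory=homology.SearchParams.translated
    )
    nucleotide_params: homology.SearchParams = field(
        default_factory=homology.SearchParams.nucleotide
    )
    seed: int = 0
    threads: int = 1

    def validate(self) -> None:
        if not Path(self.transcripts_path).is_file():
            raise ConfigError(f"transcripts file not found: {self.transcripts_path}")
        if not Path(self.protein_db_path).is_file():
            raise ConfigError(f"protein database not found: {self.protein_db_path}")
        if self.utr_db_path is not None and not Path(self.utr_db_path).is_file():
            raise ConfigError(f"UTR database not found: {self.utr_db_path}")
        if self.strand_mode not in ("unstranded", "forward", "reverse"):
            raise ConfigError(f"unknown strand mode {self.strand_mode!r}")
        if self.min_aa < 1 or self.min_utr_len < 0 or self.threads < 1:
            raise ConfigError("min_aa, min_utr_len and threads must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config mapping from YAML; keyword overrides win."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        for key in ("protein_params", "translated_params", "nucleotide_params"):
            if key in raw and isinstance(raw[key], dict):
                factory = {
                    "protein_params": homology.SearchParams.protein,
                    "translated_params": homology.SearchParams.translated,
                    "nucleotide_params": homology.SearchParams.nucleotide,
                }[key]
                raw[key] = factory(**raw[key])
        raw.update({k: v for k, v in overrides.items() if v is not None})
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None


@dataclass
class RunSummary:
    """Per-stage survivor counts and drop reasons for one run."""

    n_input_transcripts: int = 0
    n_with_orf: int = 0
    n_validated: int = 0
    n_localized: int = 0
    n_utr_pre_filter: int = 0
    n_utr_emitted: int = 0
    n_utrdb_characterized: int = 0
    n_coordinate_disagreements: int = 0
    drop_reasons: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def summarize(
    records: Sequence[utr_extract.UtrRecord],
    drop_log: Sequence[tuple[str, str]],
    n_input: int,
    n_with_orf: int,
    n_validated: int,
    n_localized: int,
    n_coordinate_disagreements: int = 0,
) -> RunSummary:
    """Aggregate emitted records and the drop log into a RunSummary."""
    reasons: dict[str, int] = {}
    for _tid, reason in drop_log:
        reasons[reason] = reasons.get(reason, 0) + 1
    return RunSummary(
        n_input_transcripts=n_input,
        n_with_orf=n_with_orf,
        n_validated=n_validated,
        n_localized=n_localized,
        n_utr_pre_filter=n_localized,
        n_utr_emitted=len(records),
        n_utrdb_characterized=sum(1 for r in records if r.utrdb_match_id),
        n_coordinate_disagreements=n_coordinate_disagreements,
        drop_reasons=reasons,
    )


def _fmt(value, is_float: bool = False) -> str:
    if value is None:
        return "."
    if is_float:
        return format(value, ".3g")
    return str(value)


def write_annotation(records: Sequence[utr_extract.UtrRecord], path: str | Path) -> None:
    """Write the tab-delimited annotation sheet; missing values are '.'."""
    with open(path, "w") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.transcript_id,
                        r.gene_name,
                        r.best_hit_id,
                        _fmt(r.best_hit_evalue, True),
                        r.strand,
                        str(r.frame),
                        str(r.stop_end_mrna),
                        str(r.utr_length),
                        _fmt(r.utrdb_match_id),
                        _fmt(r.utrdb_match_evalue, True),
                    ]
                )
                + "\n"
            )


def run_pipeline(config: RunConfig, table: CodonTable | None = None) -> RunSummary:
    """Execute ORF prediction and 3'-UTR retrieval on all transcripts.

    Writes ``utr.fasta``, ``annotation.tsv``, ``proteins.fasta``,
    ``summary.json`` and ``run.log`` into the output directory and returns
    the :class:`RunSummary`. Per-transcript failures are logged and counted,
    never fatal; only unreadable inputs abort the run.
    """
    config.validate()
    table = table or STANDARD_TABLE
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    log = logging.getLogger("threeputr.run")
    log.setLevel(logging.INFO)
    log.handlers.clear()
    log.propagate = False
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)

    transcripts = read_fasta(config.transcripts_path, moltype="dna")
    protein_records = read_fasta(config.protein_db_path, moltype="protein")
    protein_db = homology.SearchDatabase(
        protein_records, homology.BLOSUM62, config.protein_params.seed_len
    )
    utr_db = None
    if config.utr_db_path is not None:
        utr_db = homology.SearchDatabase(
            read_fasta(config.utr_db_path, moltype="dna"),
            homology.DNA_MATRIX,
            config.nucleotide_params.seed_len,
        )

    strands = {"unstranded": ("+", "-"), "forward": ("+",), "reverse": ("-",)}[
        config.strand_mode
    ]
    drop_log: list[tuple[str, str]] = []
    validated_proteins: list[SeqRecord] = []
    pre_filter: list[utr_extract.UtrRecord] = []
    n_with_orf = n_validated = n_localized = n_disagree = 0

    def drop(tid: str, reason: str) -> None:
        drop_log.append((tid, reason))
        log.info("DROP %s %s", tid, reason)

    for tx in transcripts:
        orfs = orf_finder.enumerate_orfs(
            tx, table, min_aa=config.min_aa, mode=config.strand_mode
        )
        if not orfs:
            if orf_finder.has_open_ended_run(
                tx, table, min_aa=config.min_aa, mode=config.strand_mode
            ):
                drop(tx.id, "NO_STOP")
            else:
                drop(tx.id, "NO_ORF")
            continue
        n_with_orf += 1
        candidates = orf_finder.select_candidates(orfs, mode=config.strand_mode)
        validated = homology.validate_and_annotate(
            candidates, protein_db, config.protein_params
        )
        if validated is None:
            drop(tx.id, "NO_HIT")
            continue
        cand, best_hit, gene_name = validated
        n_validated += 1
        validated_proteins.append(
            SeqRecord(
                id=cand.header(), description=gene_name, sequence=cand.aa_seq,
                moltype="protein",
            )
        )
        protein = SeqRecord(
            id=cand.header(), description="", sequence=cand.aa_seq, moltype="protein"
        )
        orf_stop_end = cand.stop_start_mrna + 3
        try:
            strand, frame, aln_stop_end = utr_extract.locate_stop_by_alignment(
                tx, protein, config.translated_params, table, strands=strands
            )
        except (utr_extract.LocalizationError, utr_extract.NoStopError) as exc:
            log.warning("%s", exc)
            drop(tx.id, "LOCALIZATION_FAILED")
            continue
        if (strand, aln_stop_end) != (cand.strand, orf_stop_end):
            n_disagree += 1
            log.warning(
                "COORD_DISAGREE %s alignment=%s/%d orf=%s/%d (ORF coordinate kept)",
                tx.id, strand, aln_stop_end, cand.strand, orf_stop_end,
            )
        n_localized += 1
        record = utr_extract.extract_utr(
            tx,
            cand.strand,
            orf_stop_end,
            gene_name=gene_name,
            best_hit_id=best_hit.subject_id,
            best_hit_evalue=best_hit.evalue,
            frame=cand.frame,
            table=table,
        )
        pre_filter.append(record)

    emitted = utr_extract.filter_by_length(pre_filter, config.min_utr_len)
    kept_ids = {r.transcript_id for r in emitted}
    for r in pre_filter:
        if r.transcript_id not in kept_ids:
            drop(r.transcript_id, "UTR_TOO_SHORT")
    if utr_db is not None:
        emitted = utr_extract.annotate_against_utrdb(
            emitted, utr_db, config.nucleotide_params
        )

    write_fasta(
        [
            SeqRecord(id=r.transcript_id, description=r.gene_name, sequence=r.utr_seq,
                      moltype="dna")
            for r in emitted
        ],
        outdir / "utr.fasta",
    )
    write_fasta(validated_proteins, outdir / "proteins.fasta")
    write_annotation(emitted, outdir / "annotation.tsv")
    summary = summarize(
        emitted, drop_log, len(transcripts), n_with_orf, n_validated, n_localized,
        n_disagree,
    )
    (outdir / "summary.json").write_text(summary.to_json() + "\n")
    log.info(
        "DONE input=%d with_orf=%d validated=%d localized=%d emitted=%d",
        summary.n_input_transcripts, summary.n_with_orf, summary.n_validated,
        summary.n_localized, summary.n_utr_emitted,
    )
    handler.close()
    log.removeHandler(handler)
    return summary
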