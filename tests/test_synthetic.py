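"""Generator determinism, category construction, and the truth-table evaluator."""

import random
from collections import Counter

import pandas as pd
import pytest

from threeputr import homology, orf_finder, synthetic
from threeputr.seqio import reverse_complement
from threeputr.synthetic import GenParams, dinucleotide_shuffle, generate_transcriptome


@pytest.fixture(scope="module")
def sim40():
    return generate_transcriptome(40, seed=5, params=GenParams(db_divergence=0.0))


def test_same_seed_reproduces_byte_identical_outputs(tmp_path):
    a = generate_transcriptome(30, seed=9)
    b = generate_transcriptome(30, seed=9)
    assert [(r.id, r.sequence) for r in a.transcripts] == [
        (r.id, r.sequence) for r in b.transcripts
    ]
    assert [(r.id, r.sequence) for r in a.proteins] == [
        (r.id, r.sequence) for r in b.proteins
    ]
    pd.testing.assert_frame_equal(a.truth, b.truth)
    a.write(tmp_path / "a")
    b.write(tmp_path / "b")
    for name in ("transcripts.fasta", "proteins.fasta", "utrdb.fasta", "truth.tsv"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_category_fractions_realized_exactly():
    counts = Counter(g.category for g in generate_transcriptome(40, seed=2).genes)
    assert counts == {
        "normal": 28, "decoy_noncoding": 6, "truncated_no_stop": 4, "short_utr": 2,
    }


def test_zero_divergence_db_proteins_match_truth(sim40):
    by_gene = {
        g.gene_id: g.protein_true for g in sim40.genes if g.category != "decoy_noncoding"
    }
    assert len(sim40.proteins) == len(by_gene)
    for rec in sim40.proteins:
        gene_id = rec.description.split("GN=")[1].split()[0]
        assert rec.sequence == by_gene[gene_id]


def test_db_divergence_rate_is_approximately_realized():
    res = generate_transcriptome(60, seed=3, params=GenParams(db_divergence=0.2))
    truth_by_gene = {
        g.gene_id: g.protein_true for g in res.genes if g.category != "decoy_noncoding"
    }
    diffs = total = 0
    for rec in res.proteins:
        gene_id = rec.description.split("GN=")[1].split()[0]
        true = truth_by_gene[gene_id]
        assert len(rec.sequence) == len(true)
        diffs += sum(a != b for a, b in zip(rec.sequence, true))
        total += len(true)
    assert 0.15 < diffs / total < 0.25


def test_normal_transcript_architecture(sim40):
    for g in sim40.genes:
        if g.category not in ("normal", "short_utr"):
            continue
        sense = g.transcript_sense
        assert len(sense) == g.utr5_len + g.cds_len + 3 + g.utr3_len
        cds = sense[g.utr5_len : g.utr5_len + g.cds_len]
        assert cds.startswith("ATG")
        assert sense[g.utr5_len + g.cds_len : g.utr5_len + g.cds_len + 3] in {
            "TAA", "TAG", "TGA",
        }
        assert sense.endswith(g.utr3_seq) or g.utr3_len == 0
        expected_contig = sense if g.contig_orientation == "+" else reverse_complement(sense)
        assert g.contig_seq == expected_contig


def test_decoys_have_no_homology_supported_orf(sim40):
    db = homology.SearchDatabase(sim40.proteins, homology.BLOSUM62, 3)
    params = homology.SearchParams.protein()
    decoys = [g for g in sim40.genes if g.category == "decoy_noncoding"]
    assert decoys
    for g in decoys:
        rec = [t for t in sim40.transcripts if t.id == g.transcript_id][0]
        cands = orf_finder.select_candidates(
            orf_finder.enumerate_orfs(rec, min_aa=50), mode="unstranded"
        )
        assert homology.validate_and_annotate(cands, db, params) is None


def test_truth_outcomes_consistent_with_categories(sim40):
    for g in sim40.genes:
        if g.category == "normal":
            assert g.expected_outcome == "emitted"
        elif g.category == "short_utr":
            assert g.expected_outcome == "dropped:UTR_TOO_SHORT"
        else:
            assert g.expected_outcome.startswith("dropped:")


def test_dinucleotide_shuffle_preserves_dinucleotide_counts():
    rng = random.Random(8)
    seq = "".join(rng.choice("ACGT") for _ in range(400))
    shuffled = dinucleotide_shuffle(seq, rng)
    assert len(shuffled) == len(seq)
    assert Counter(zip(seq, seq[1:])) == Counter(zip(shuffled, shuffled[1:]))
    assert shuffled[0] == seq[0] and shuffled[-1] == seq[-1]


def test_invalid_fractions_rejected():
    with pytest.raises(ValueError, match="sum to 1"):
        generate_transcriptome(10, seed=0, params=GenParams(frac_normal=0.9))


def test_evaluate_identity_and_empty_and_shifted(tmp_path, sim40):
    sim40.write(tmp_path / "sim")
    truth_path = tmp_path / "sim" / "truth.tsv"
    # perfect predictions constructed directly from the truth table
    emitted = [g for g in sim40.genes if g.expected_outcome == "emitted"]
    ann = tmp_path / "annotation.tsv"
    fa = tmp_path / "utr.fasta"
    header = (
        "transcript_id\tgene_name\tbest_hit_id\tbest_hit_evalue\tstrand\tframe"
        "\tstop_end_mrna\tutr_length\tutrdb_match_id\tutrdb_match_evalue\n"
    )
    with open(ann, "w") as fh, open(fa, "w") as fh2:
        fh.write(header)
        for g in emitted:
            fh.write(
                f"{g.transcript_id}\t{g.gene_id}\thit\t0\t+\t0\t{g.stop_end_mrna}"
                f"\t{g.utr3_len}\t.\t.\n"
            )
            fh2.write(f">{g.transcript_id}\n{g.utr3_seq}\n")
    m = synthetic.evaluate(ann, fa, truth_path)
    assert m["recall_exact"] == 1.0 and m["precision"] == 1.0 and m["stop_mae"] == 0.0

    # empty predictions: zero recall by definition
    (tmp_path / "empty.tsv").write_text(header)
    (tmp_path / "empty.fasta").write_text("")
    m = synthetic.evaluate(tmp_path / "empty.tsv", tmp_path / "empty.fasta", truth_path)
    assert m["recall_exact"] == 0.0 and m["n_predicted"] == 0.0

    # one stop coordinate shifted by 3 -> mean offset 3 / n_emitted
    lines = ann.read_text().splitlines()
    cols = lines[1].split("\t")
    cols[6] = str(int(cols[6]) + 3)
    lines[1] = "\t".join(cols)
    (tmp_path / "shifted.tsv").write_text("\n".join(lines) + "\n")
    m = synthetic.evaluate(tmp_path / "shifted.tsv", fa, truth_path)
    assert m["stop_mae"] == pytest.approx(3 / len(emitted))

    # unknown transcript ids are a contract violation
    (tmp_path / "bogus.tsv").write_text(
        header + "zz99\tg\th\t0\t+\t0\t10\t5\t.\t.\n"
    )
    with pytest.raises(ValueError, match="unknown transcript"):
        synthetic.evaluate(tmp_path / "bogus.tsv", fa, truth_path)
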