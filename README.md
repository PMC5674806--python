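# threeputr

Genome-independent 3′-UTR prediction from de novo transcriptome assemblies.

The 3′ untranslated region — the stretch of an mRNA between the stop codon
and the polyadenylation site — carries miRNA response elements, AU-rich
elements and polyadenylation signals, and is the substrate for most
post-transcriptional regulation analyses. For non-model organisms there is
usually no annotated reference genome to lift 3′-UTR coordinates from; all
one has is a pile of assembled transcripts. `threeputr` extracts 3′-UTRs
from exactly that input: assembled contigs (FASTA) plus a curated protein
database (Uniprot-like FASTA), nothing else.

## Method

For each contig the pipeline:

1. **predicts ORFs by six-frame conceptual translation** (both
   orientations, since assemblers emit forward and reverse-complement
   contigs; three frames for stranded libraries). An ORF is a maximal
   stop-to-stop run of codons; runs that never reach a stop codon are
   discarded — without a stop there is no 3′-UTR boundary;
2. **validates by homology**: the longest ORF per orientation is aligned
   against the protein database with the built-in seed-and-extend
   local-alignment engine (BLOSUM62, affine gaps, Karlin–Altschul
   E-values: bit score S′ = (λS − ln K)/ln 2, E = mn·2^(−S′)). The longer
   candidate is tried first; if it has no hit under the stringency filters
   (E ≤ 1e−5, identity ≥ 35%, query coverage ≥ 50% by default) the shorter
   one is tried. Transcripts with no hit — noncoding RNA, assembly
   artifacts — are excluded. The best hit's gene name annotates the
   transcript;
3. **locates the stop codon strand-aware** by aligning the transcript's
   six-frame translations against its *own* predicted protein, mapping the
   best frame's alignment end to nucleotide coordinates and extending in
   frame to the first stop codon. The same coordinate is independently
   available from the ORF itself; the two routes are cross-checked on every
   transcript;
4. **trims** everything up to and including the stop codon, emitting the
   remaining suffix in mRNA sense (5′→3′ of the coding strand) as the
   predicted 3′-UTR, subject to a user-modifiable minimum length
   (default 20 nt);
5. optionally **labels** each predicted UTR against a curated UTR
   collection (UTRdb-like FASTA) by nucleotide alignment; candidates
   without a match are kept as potentially novel 3′-UTRs.

A seeded synthetic-transcriptome generator (`simulate`) produces
ground-truth fixtures — multi-gene transcript sets with mixed
orientations, noncoding decoys, stop-less truncated ORFs, short-UTR genes,
and a protein database diverged a few percent from the transcript-encoded
proteins — so the entire pipeline is testable closed-loop without
downloading anything.

## Worked example

```bash
threeputr simulate --n-genes 50 --seed 7 --db-divergence 0.05 --out-dir sim
threeputr run --transcripts sim/transcripts.fasta \
              --protein-db sim/proteins.fasta \
              --utr-db sim/utrdb.fasta --out-dir out
threeputr evaluate out/annotation.tsv out/utr.fasta sim/truth.tsv
```

The `run` step prints the stage summary:

```json
{
  "drop_reasons": {"NO_HIT": 13, "UTR_TOO_SHORT": 2},
  "n_coordinate_disagreements": 0,
  "n_input_transcripts": 50,
  "n_localized": 37,
  "n_utr_emitted": 35,
  "n_utrdb_characterized": 18,
  "n_validated": 37,
  "n_with_orf": 50
}
```

Of 50 simulated contigs, 13 (the noncoding decoys and the truncated,
stop-less transcripts) fail homology validation, 2 genes with sub-threshold
UTRs fall to the length filter, and 35 3′-UTRs are emitted, 18 of which
match the curated collection (the rest are "novel" by construction, since
the simulated UTRdb covers half the true UTRs). `evaluate` scores the run
against the generator's truth table:

```json
{
  "gene_name_accuracy": 1.0,
  "precision": 1.0,
  "recall_exact": 1.0,
  "stop_mae": 0.0
}
```

every emitted UTR matches the true UTR sequence exactly, no decoy or
truncated transcript leaks through, and the stop-codon coordinate is exact.

Outputs of a run: `utr.fasta` (predicted 3′-UTRs, mRNA sense),
`annotation.tsv` (tab-delimited: transcript, gene name, best hit and
E-value, strand, frame, stop coordinate, UTR length, curated-UTR match),
`proteins.fasta` (validated ORF proteins), `summary.json`, `run.log`
(one machine-parsable line per dropped transcript). The two pipeline
stages are also available separately as `predict-orf` and `extract-utr`.

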