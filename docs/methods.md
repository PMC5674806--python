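# Methods

## Coordinate and sequence conventions

All coordinates are 0-based, half-open, and expressed on the mRNA-sense
strand — the orientation in which the validated ORF reads 5′→3′. A
minus-strand ORF's coordinates therefore refer to the reverse complement of
the contig as assembled; contig-strand coordinates are derived on demand and
never stored, which removes the usual class of strand off-by-one errors.
Predicted 3′-UTRs are always written in mRNA sense, matching how
miRNA-target and regulatory-element tools expect them. The only 1-based
coordinates anywhere are in the optional 12-column tabular alignment report,
which mirrors the de facto tabular format for interoperability.

Sequences are uppercased on input; soft-masking case is discarded. The
genetic code defaults to the standard table and is overridable via a
two-column text file (codon, amino acid), since non-standard taxa may need
it.

## ORF model

An ORF is a maximal stop-to-stop (or sequence-start-to-stop) run of codons.
No initiator ATG is required by default because de novo assemblies are
frequently 5′-truncated; a `require_start_codon` flag trims runs to their
first ATG for users who want conservative calls. Runs that reach the 3′ end
of the contig without a stop codon are never emitted: the stop codon is the
anchor the extraction step needs, and a missing stop means the 3′-UTR is not
in the contig at all. Such transcripts are dropped with reason `NO_STOP`
(when a sufficiently long open run exists) or `NO_ORF`.

Ambiguity codons translate to 'X' unless every IUPAC expansion agrees on one
amino acid (GCN → A); expansions that include a stop never collapse to '*',
and stop detection requires a literal TAA/TAG/TGA — a stop is never asserted
from an N. 'X' residues count toward ORF length and score 0 against
everything in the aligner, so ambiguity neither creates nor destroys
candidates.

`min_aa` (default 50 residues) sets the smallest candidate worth validating;
shorter runs are indistinguishable from noise and would only inflate the
search load. Ties in length are broken deterministically: lower frame, then
smaller start within a strand; '+' before '−' between strands.

Unstranded libraries contribute the longest ORF per orientation (at most
two candidates); the longer is validated first and the shorter is the
fallback when the longer has no database hit — the fallback exists because
a long spurious reading frame on the wrong strand is common in practice.
Stranded libraries restrict the scan to the sequenced orientation and
validate the single longest candidate.

## Alignment engine

The homology stage is a self-contained seed-and-extend local aligner rather
than a wrapper around an external search binary, so results are
deterministic and the package has no runtime tool dependencies.

* **Scoring.** BLOSUM62 for protein and translated modes with affine gaps
  (open 11, extend 1; a gap of length L costs open + L·extend); +2/−3 with
  gaps 5/2 for nucleotide mode. 'X' and 'N' score 0 against everything;
  '*' (stop, present only in conceptual translations) scores −4 so local
  alignments never cross a stop.
* **Seeding.** Exact k-mer matches (k = 3 protein, 11 nucleotide) grouped
  by (subject, diagonal); seeds containing wildcards are skipped. The best
  seed per diagonal is extended ungapped with an x-drop of 20; a subject
  whose best ungapped extension reaches the `ungapped_trigger` raw score
  (default 25) proceeds to banded affine DP (half-width 32) centred on that
  diagonal. The trigger stage is what keeps a many-transcript run tractable:
  random 3-mer seeds are ubiquitous between unrelated proteins, and gapped
  DP on every seeded subject would dominate the runtime.
* **Exhaustive mode.** A `full_dp` flag bypasses seeding and runs full
  Smith–Waterman–Gotoh per subject. The seeded path can never exceed it;
  the test suite exploits this as an internal oracle, alongside an
  independent naive recursion and Biopython's `PairwiseAligner`.
* **Statistics.** Karlin–Altschul: S′ = (λS − ln K)/ln 2 and
  E = m·n·2^(−S′), with m the query length as searched (frame residues in
  translated mode) and n the total database residue count unless
  overridden. λ and K default to the published gapped parameterization for
  the default scoring systems (0.267/0.041 protein, 0.625/0.41 nucleotide)
  and are plain overridable fields; no edge-effect length correction is
  applied — at the stringency used (E ≤ 1e−5) the correction would not
  change any accept/reject decision the package makes.
* **Filters.** Defaults operationalize "stringent" search: E ≤ 1e−5,
  identity ≥ 35% (80% nucleotide), query coverage ≥ 50%. Translated mode
  does not filter on query coverage: the query there is a whole-transcript
  frame translation whose UTR content makes coverage meaningless. One
  aggregated alignment is kept per query–subject pair; HSP tiling and
  sum statistics are out of scope.
* **Tie-breaks.** Traceback prefers diagonal over up over left; the best
  cell is the first maximum in row-major order; hits sort by E-value, then
  raw score, then subject id. Together these make every output byte
  deterministic.

The DP fill kernels are JIT-compiled with numba when it is importable; the
pure-Python fallback is the same code and produces identical results,
only slower.

## Stop-codon localization and trimming

The extraction step aligns each transcript's conceptual translations
against the transcript's own validated protein (a single-entry database)
and keeps the best frame/strand. The alignment end maps to nucleotide
position frame + 3·(aa end); from there the scanner walks in frame to the
first literal stop codon. Walking, rather than trusting the alignment end
directly, matters when the protein diverges or the alignment is gapped near
the C-terminus — the stop codon is the biological anchor, the alignment is
only the pointer to the right frame. The coordinate obtained this way is
compared, for every transcript, against the ORF enumeration's own
stop coordinate; the ORF coordinate wins on disagreement, which is logged
and counted in the run summary (`n_coordinate_disagreements`). On the
synthetic fixtures at zero database divergence the two routes never
disagree, and the acceptance checks pin that down.

Trimming removes the 5′-UTR, ORF and stop codon; the suffix is the
predicted 3′-UTR. The length filter (default 20 nt, inclusive, user-set)
removes candidates indistinguishable from assembly noise. Curated-UTR
labeling is annotation only: candidates without a match are retained as
potentially novel, never removed.

## Pipeline contract

Transcripts are independent work units processed sequentially in input
order; a `threads` field is accepted for interface compatibility and the
order-stable output guarantee holds trivially. Identical inputs and
configuration produce byte-identical outputs. Every input transcript
appears exactly once in either `annotation.tsv` or the drop log, with one
of five reason codes (`NO_ORF`, `NO_STOP`, `NO_HIT`,
`LOCALIZATION_FAILED`, `UTR_TOO_SHORT`), and the per-stage counts in
`summary.json` reconcile exactly with the reason tallies. Configuration
comes from a YAML file, command-line flags, or both; flags win.

## Synthetic transcriptomes

The generator emulates the input regime the pipeline targets: per-gene
architecture 5′UTR (uniform 20–150 nt) + ATG-initiated CDS (uniform
100–400 codons, back-translated with uniform synonymous codon choice —
codon bias is irrelevant to every implemented stage) + stop + 3′UTR
(log-normal, median ≈ 400 nt, σ = 0.7, clipped to [1, 5000], loosely
matching vertebrate annotations), 55% AT in the UTRs, half the contigs
reverse-complemented. Default category mix: 70% normal, 15% noncoding
decoys (dinucleotide-preserving Altschul–Erikson shuffles, resampled until
no ORF candidate survives homology validation), 10% stop-less truncated
transcripts, 5% genes with sub-threshold UTRs. The protein database holds
one copy of each coding gene's protein with `GN=<gene>` headers, diverged
at 5% per residue by default to emulate a cross-species reference; the
simulated curated-UTR collection contains exact copies of half the true
UTRs so the characterized/uncharacterized split is exercised.

Coding genes' UTR sequences are resampled (up to 60 draws) until the true
CDS run is the candidate that longest-per-strand selection retains — a very
long random UTR can otherwise spawn a longer spurious frame and the gene
would legitimately drop; the truth table's expected outcomes are exact
because the generator enforces this invariant rather than hoping for it.
Expected outcomes for decoys and truncated genes are computed from the same
selection rules the pipeline uses.

What the generator does **not** model: sequencing errors and misassembly
indels (which would frameshift ORFs), real codon usage and composition
biases, paralogous families, alternative polyadenylation isoforms, and
expression levels. Passing the closed-loop checks therefore demonstrates
the correctness of the coordinate arithmetic, strand handling, selection/
fallback/exclusion rules and alignment engine — not robustness to
assembly artifacts, which on real data is governed by the upstream
assembler and the stringency settings.

## Problem sizes and verification

The acceptance checks run the full loop on 200-gene transcriptomes: one
divergence-free fixture for exactness, strand invariance (global
reverse-complementation changes only the reported strand) and dual-route
stop-coordinate agreement, and five seeds at 5% database divergence for
robustness (mean exact recall ≥ 0.95; measured 1.0). The aligner is checked
against three independent oracles: an exhaustive recursion on all pairs up
to length 12, Biopython's optimal local aligner on longer random pairs, and
the engine's own `full_dp` mode on seeded homolog sets. E-value analytics
(S = 0 closed form, database-size linearity, strict monotonicity in score)
are verified exactly.

## Known limitations

* One UTR per transcript: alternative 3′-UTR isoforms across contigs are
  not clustered or reconciled.
* No polyadenylation-site refinement; the UTR ends where the contig ends.
* Frameshifts within the CDS defeat the single-frame alignment model; such
  transcripts surface as localization failures or coordinate disagreements
  rather than silently wrong UTRs.
* Karlin–Altschul constants are taken for the default scoring systems;
  users who change matrices or gap costs should supply matching λ and K.
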