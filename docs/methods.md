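# Methods

## Model and assumptions

The scaffolder treats a paired-end RNA-seq pair whose mates align uniquely
to two different contigs as evidence of a physical join. The underlying
assumptions are:

* **Exon-sized mates.** Metazoan exons have a median length near 170 bp,
  smaller than the combined length of a read pair, so the two mates of a
  junction-spanning pair typically sit in two different exons and the
  sequence between their footprints is intronic. The minimal inserted
  size of a join is therefore bounded by a maximal intron length (MIL,
  default 100 kb): joins implying longer introns are treated as
  misalignments.
* **FR library geometry.** Mate 1 reads the fragment's forward strand and
  mate 2 its reverse complement. Mate 1's contig becomes the donor with
  mate 1's strand as its orientation; the acceptor orientation is the
  opposite of mate 2's strand. An RF library would flip the acceptor
  rule; the implementation assumes FR, the dominant convention for
  Illumina paired-end RNA-seq.
* **Maximal support wins.** The number of guide pairs behind an oriented
  join is its weight. At each contig end only a unique maximal-weight
  connection is trusted; a tie is read as a repeat or systematic
  misalignment and discards *all* connections at that end.

Internal coordinates are 0-based half-open everywhere. SAM input is
converted at the boundary (POS − 1; reference span from the CIGAR with
N/D consuming reference); PSL is native. Under this convention the
minimal-insert formula for a forward/forward join is exactly
`Length(A) − end(a) + start(b)`, and the general form is the sum of the
two outward flanks (donor flank `start(a)` when the donor is reversed,
acceptor flank `Length(B) − end(b)` when the acceptor is reversed).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_pairs` | 2 | supporting pair number per connection; 1 admits noise-level joins, larger values trade contiguity for accuracy |
| `mlc` | 0.9 | minimal length coverage: a realignment covering ≥ this fraction of the query counts as a strong hit; a mate with strong hits on ≥ 2 contigs is ambiguous. The comparison is inclusive so `mlc=1.0` still recognises perfect full-length hits |
| `mil` | 100 000 bp | maximal intron length; connections with minimal inserted size ≥ MIL are rejected (strict "smaller than") |
| `default_gap` | 100 bp | N-run used when the minimal inserted size already exceeds the median intron |

Uniqueness of a mate's alignment is mapper-dependent, so it is a
configurable rule: `tag` (hit-count tag `NH == 1`, falling back to record
counting when the tag is absent; the default), `mapq` (MAPQ ≥ 30), or
`single-record` (exactly one record for the mate, secondary records
included in the count). Mate identity in PSL, which has no flag field, is
parsed from `/1|/2` or `_1|_2` query-name suffixes (configurable regex).

## Design choices where the design was open

* **Canonical connections.** A physical join has two equivalent directed
  readings (donor→acceptor and its reverse-complement mirror). Both are
  reduced to the reading whose donor id is lexicographically smaller, so
  mirrored evidence aggregates into one connection.
* **Per-end optimisation.** "Best connection per donor / per acceptor" is
  implemented per *contig end* (head/tail in + orientation): a contig may
  legitimately extend on both sides, and per-end degree ≤ 1 is exactly
  the condition that makes the surviving graph a union of simple paths.
* **Merged minimal insert.** When pairs merge into one connection, the
  connection's minimal inserted size is the minimum over pairs — the most
  conservative estimate of intervening sequence.
* **Cycles.** Per-end selection can still leave cycles; they are broken
  deterministically at the minimum-weight connection (ties: smallest
  canonical key). Finished paths are flipped, if needed, so the first
  contig id is not greater than the last, making output independent of
  walk direction.
* **Median intron.** Even-count medians take the lower middle value
  (integer, deterministic). Same-contig pairs enter the intron pool only
  when FR-consistent (opposite strands, leftmost mate on +); overlapping
  mates contribute an inner length of 0. An optional minimum inner length
  can exclude unspliced pairs. With an empty pool the median is 0 and all
  junctions receive the default gap.
* **Gap rule.** "The insert of one connection" in the gap rule is that
  connection's minimal inserted size, not the global MIL parameter — the
  only reading under which the per-junction difference is well defined.
* **Evaluation.** Consistency additionally requires rank-adjacency in the
  truth; correctable relocation exists precisely for joins that skip
  short (< MIL) intervening sequence. Orientation-consistent but
  order-reversed joins count as erroneous relocations. The reference
  distance is the facing-edge gap between the two truth spans. UNKNOWN
  junctions stay in the accuracy denominator by default (they are not
  demonstrably correct); a flag excludes them.

## The synthetic-data generator

The simulator emulates the inputs the scaffolder consumes in practice:

* units (chromosomes) of random sequence carrying non-overlapping
  multi-exon genes on both strands; exon lengths log-uniform around a
  median of 170 bp (bounded 120–400), introns around a configurable
  median (default 400 bp, bounded 120–2000), 3–5 exons per gene so that
  the default density of 40 genes fits a 100 kb unit with headroom;
* contig fragmentation at breakpoints placed inside introns with
  probability `break_preference` (drawn from *distinct* introns — a
  second break in one intron would create a pure-intron sliver contig no
  transcript can reach), else uniformly; concatenating a unit's contigs
  in rank order reconstructs it exactly, so true junction distances are 0;
* FR pairs drawn from spliced transcripts and projected through the exon
  chain onto contig coordinates, giving spliced SAM (with `N` operations
  for introns retained within one contig) and mirroring PSL records at
  coverage 1.0; junction-targeted fragments guarantee a configurable
  support per spannable junction, background fragments populate the
  same-contig intron pool;
* noise: a fraction of pairs get one mate re-assigned to a uniform wrong
  position (the mechanism behind spurious weight-1 connections); half of
  those noise mates also gain a second above-MLC PSL hit, giving the MLC
  filter true positives to remove; a separate fraction of mates is
  emitted as multi-mappers (`NH:i:2` plus a secondary record) that the
  uniqueness rule must exclude.

What the simulator does **not** model: base-level sequencing errors
(alignment coordinates are authoritative), expression-level variation
beyond per-junction pair counts, alternative splicing, paralogy/repeats
beyond the multi-map knob, and real mapper behaviour. Passing tests
therefore demonstrate the correctness of the algorithmics and the
qualitative parameter trade-offs, not performance on real libraries.

## Study conditions

Two named conditions drive the self-characterisation harnesses
(`rnascaffold.studies`):

* **Dense** — 5 × 100 kb units, 40 genes/unit, 199 intronic breaks
  (204 contigs: the breaks plus the five unit boundaries), 10 error-free
  pairs per junction. Nearly every junction is transcript-spanned, so
  near-complete recovery at default parameters is the expected outcome.
* **Sparse** — 15 genes/unit, `break_preference` 0.4, 30 background
  pairs per gene, 5% mis-mapped pairs. This emulates the regime in which
  real mis-joins arise: most contig ends carry no transcript evidence
  (giving spurious connections somewhere to attach) and informative guide
  pairs are a minority of all pairs. Under full transcript coverage a
  weight-1 noise connection is always outcompeted by the weight-10 true
  connection at the same end, and no false junction can surface — the
  trade-off between the supporting pair number and accuracy is only
  observable when free ends exist. The noise study runs three replicate
  genomes per seed, since a single ~200-junction genome may by chance
  offer the handful of surviving noise connections no free end pair.

Problem sizes throughout (hundreds of contigs, thousands of pairs) keep
any single study under a few seconds on one core while leaving every
pipeline stage with non-trivial work.

## Numerical and degenerate-input behaviour

* Ties in per-end selection: all connections at the tied end discarded.
* Empty inputs: an empty FASTA yields an empty contig set; an empty PSL
  is a valid empty realignment set; a missing PSL skips re-filtration
  with a warning (the filter becomes the identity).
* A computed gap of 0 cannot occur: the strict `insert < median` branch
  implies a difference ≥ 1, so no minimum-gap clamp is needed.
* `n50` requires a non-empty, positive length set; `accuracy` raises on
  zero junctions rather than returning a silent 0/0.

## Known limitations

* No contig breaking: mis-assembled input contigs propagate.
* No repeat-aware multi-path resolution; repeats reduce recall (by
  design, through the tie rule) rather than precision.
* Gap sizes are a genome-wide median heuristic; per-junction splice-span
  refinement is out of scope.
* The evaluator needs truth placements supplied directly; it does not
  align assemblies to references.
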