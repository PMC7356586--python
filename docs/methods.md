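# Methods

This note documents the model behind `adapterid`, the tunable parameters,
the numerical conventions, what the synthetic data generator does and does
not emulate, and the known limitations.

## Signal model

A raw single-read record is a concatenation

    [5' adapter]  [barcode]  [5' N-mer]  insert  [3' N-mer]  [3' adapter]  [post-adapter content]

truncated to the machine read length (Illumina, SOLiD) or emitted at
natural length (454, Ion Torrent). The insert is biological and varies
between reads; the adapters are constant library-preparation
oligonucleotides. Inference rests on three empirical assumptions: (i) a
non-negligible minority of reads carries the 3′ adapter intact; (ii) the
*head* (5′-most bases) of the 3′ adapter is essentially never degraded —
real-world degradation is tail truncation by the read boundary plus
scattered sequencing errors; (iii) the insert bases immediately preceding
the adapter are not constant across the library. When (i) fails entirely
the correct output is `no_adapter_found`, and the pipeline is required to
say so rather than promote chance sequence (negative-control behaviour).

## The aligner

A self-contained ungapped seed-and-extend local aligner replaces an
external alignment tool, making the package dependency-free and exactly
testable: every exact `word_size`-mer shared between a query and a subject
is extended in both directions, stopping when the running score falls more
than `xdrop` below its maximum, then trimmed back to the maximum-score
extent (strictly-greater updates, so the shortest maximal extent wins).
Overlapping HSPs of one query–subject pair are culled to maximal-score
representatives (ties: smaller query start, then smaller subject start).
Coordinates are 1-based inclusive, the convention the downstream
position thresholds are written in. Plus strand only — adapters have a
fixed orientation in single-read data.

Defaults: `word_size=7`, `match=+1`, `penalty=−2`, `xdrop=6`,
`min_score=7`. The floor equals `word_size · match` so that the shortest
adapters in circulation (7 nt) are reportable as bare seeds; the chance
7-mer alignments this admits (≈ 10⁻⁴·positions² per pair) are removed by
the consensus support guards, not by the score floor. The per-pair HSP cap
is 2: one slot for the adapter, one for a biologically shared sequence,
which the filter cascade later removes by position. Global per-query /
per-subject caps exist but default to off.

For reference-genome search (N-mer detection) the seed is lengthened to
`word_size=12`, `min_score=18`: queries contain ≥ ~21 nt of exact genomic
sequence and the longer word keeps chance hits against 10⁵-bp references
negligible while cutting index time.

## Filter cascade and consensus

The filter branch is chosen once from the median aligned length *m* of all
HSPs (branch thresholds: *m* > 20, 10 ≤ *m* ≤ 20, *m* < 10, as described
in the README), and the filters run as a single pass. The consensus
dispatch (short vs long path) then uses the median of the *surviving*
alignments, the set the consensus actually consumes.

Short path (*m* ≤ 10): aligned sequences shorter than 15 nt are sorted
alphabetically; a *frame* is a maximal sorted run whose first (shortest)
member is a prefix of every member — one adapter observed at different
read-through depths. The dominant frame's most common member is the call;
when a second frame holds comparable support (≥ 25 % of the top frame) the
call is the longest common prefix of the two frames' shortest members,
covering the case of a constant biological base abutting the adapter.

Long path (*m* > 10): within each query, true adapter alignments share the
query start (the adapter abuts that query's insert); only alignments
within `start_window = 3` nt after the modal start are kept, which also
absorbs randomized-junction N-mers. Sequences are truncated to
`trunc_len = 20` nt (only the head matters for trimming), pooled, counted
and frame-grouped. Frames whose head is a *shifted copy* of the dominant
head (offset ≤ 3, exact overlap ≥ 7) are consolidated: alignments into
head-damaged partners systematically produce a left-truncated copy of the
head, and chance flank extensions a left-extended one. The consolidated
group is represented by the frame extending furthest left among those with
at least half the group's maximum support — systematic truncated copies
can tie the true head in count, whereas chance left-extensions split
across four possible flank bases and never reach parity. If the top frame
then holds at least twice the runner-up's support its most common member
is the call; otherwise the call is the longest common prefix of the two
heads (< 3 nt ⇒ no call).

Support guards: the winning frame needs ≥ `min_frame_support = 5` records,
and on the short path additionally ≥ 20 % of all retained records. These
guards are the effective false-positive control: in adapter-free libraries
the chance alignments that reach the consensus are scattered across dozens
of singleton frames (top frame ≤ ~8 % of records in our negative
controls), while a true adapter concentrates well over half.

Selection rules: queries and subjects are taken in abundance-rank order,
skipping sequences with N, shorter than `min_insert = 15`, homopolymers
(one base ≥ 80 %) and low-complexity sequences (overlapping-dinucleotide
Shannon entropy < 1.5 bits). In Illumina/SOLiD mode one sequence is kept
per distinct 20-nt prefix so that near-duplicate reads of one
over-abundant species cannot fill the selection; the rule stays off in
dual mode, where every read legitimately shares the 5′-adapter prefix.
Barcode detection orders count-ties by a content hash: with an all-unique
library an alphabetical order would hand the detector reads that share a
prefix by construction.

## Dual-adapter and SOLiD variants

454 / Ion Torrent: 15 queries vs 100 subjects, two HSPs per pair, pooled
truncated sequences counted; the two most frequent are the candidates and
the one whose supporting alignments have a modal query start in 1–6 is the
5′ adapter (its 5′-degraded forms still start at position 1 of the read).
Ambiguity (both or neither in window) or fewer than two supported
candidates ⇒ `no_adapter_found` with the evidence retained.

SOLiD: colorspace reads (primer base + color digits, colors the XOR of
adjacent 2-bit base codes) are decoded left-to-right; a missing color
('.') decodes to N and, being a transition code, poisons all subsequent
bases. Decoding failures above 10 % abort with a corrupt-input error.
Inference then runs exactly as for Illumina on the decoded reads; trimming
is performed in color space by encoding the called adapter.

## Trimming

Mismatch-only (no indels), mirroring the inference stage: 3′ trimming
removes the leftmost adapter occurrence (full match anywhere, or a prefix
≥ `min_overlap = 3` at the read end) and everything after it, tolerating
`floor(error_rate · matched)` mismatches with `error_rate = 0.1`; 5′
adapter trimming removes through the last base of the rightmost occurrence,
accepting adapter suffixes overhanging the read start (degraded 5′ ends).
An *anchored barcode* is instead stripped as an exact fixed-position
prefix — a positional match rule applied to a 4-mer would fire on internal
insert sequence. Re-trimming an already-trimmed library only fires on
chance end matches, at rate Σ_{k≥3} 4^{−k} ≈ 2.1 % per read. The fraction
of reads changed by 3′ trimming (`pct_with_3p`) is reported as the primary
indicator that the inferred sequence was right; genome mapping is out of
scope.

## Random-mer detection

The top 750 collapsed reads of length ≥ 29 (same eligibility rules) are
aligned against both strands of the reference; per query the best hit
(highest score, then plus strand, then smallest coordinate) gives a start
offset `q_start − 1` and an unaligned tail `len − q_end`. A terminal
N-mer is called when the modal value lies in 1..8 and is supported by at
least 50 % of aligned queries (fewer than 25 aligned queries ⇒ error).
The 50 % support level and the length cap are conventions: protocols use
2–4 randomized bases, and chance flank matches erode the mode by at most
~25 % per terminus. Inputs must be adapter-trimmed first — residual 3′
adapter would masquerade as a 3′ N-mer.

## The synthetic data generator

`simulate_library` assembles every platform layout from explicit parts and
records per-read ground truth sufficient to rebuild each read byte-exactly.
Design choices:

* **Abundance**: inserts are drawn from a finite species pool (default
  2000) with Zipf-skewed probabilities (exponent 1.1), emulating the
  skewed species abundance of small RNA libraries that makes read
  collapsing informative. Insert lengths are uniform on the configured
  range (default 18–26 nt); reads default to 10,000 per library at a
  50-nt machine read length.
* **Post-adapter content** is i.i.d. random sequence — the adversarial
  choice for inference, since constant post-adapter content would only
  make consensus easier.
* **Degradation** of the 3′ adapter on the non-intact read fraction:
  `homogeneous` applies one library-wide fixed substitution;
  `heterogeneous` draws per read from a truncation-dominant mixture (60 %
  tail truncation to a uniform shorter length, 25 % one or two random
  substitutions, 15 % both). Truncation dominates because the main
  real-world cause of a non-intact 3′ adapter is the read ending inside
  it; the substitution multiplicity reflects realistic error rates. A
  fully-degraded scenario (every copy modified) is generable and is
  expected to defeat inference.
* **5′ degradation** (454/Ion Torrent): a configurable fraction of reads
  keeps only a suffix (≥ 12 nt) of the 5′ adapter.
* SOLiD output is colorspace-encoded with primer base T (configurable).

What the generator does **not** emulate: per-base quality-dependent error
models, indels inside reads, PCR duplicates, flowgram homopolymer errors,
and adapter dimers. Passing tests therefore demonstrate correctness of the
inference logic under realistic library structure, not robustness to every
sequencing artefact.

## Problem sizes and numerical conventions

Simulated validation uses 10,000-read libraries (5,000 for N-mer runs
against a 100-kb reference), three independent seeds per condition, and an
intact-fraction sweep over a 10-point geometric grid from 0.5 down to
0.01. All randomness flows through seeded NumPy generators; collapsing
breaks count ties lexicographically, HSP ties break by score, then start
coordinates, then partner index, so every pipeline output is a
deterministic function of the input multiset.

## Limitations

* Mismatch-only inference and trimming: adapters with internal indels are
  recovered only up to the indel.
* A constant biological base shared by *all* inserts immediately before
  the adapter will be absorbed into the called adapter (shared-biology
  assumption (iii) above).
* The already-trimmed check assumes fixed-length sequencer output; it is
  not applied to natural-length 454/Ion Torrent data.
* Paired-end protocols, BAM/SAM input, quality trimming and demultiplexing
  are out of scope.
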