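# Methods

This note documents the models, data structures, numerical choices and
limitations behind liftkit, in the order a record travels through the
pipeline.

## Chain model and coordinate conventions

A chain file is parsed into chains of gapless aligned blocks
(`ChainInterval`) separated by gaps (`ChainGap` with `dsource` bases of
source-only and `dtarget` bases of target-only sequence; interior gaps
satisfy dsource + dtarget > 0, and 0/0 gap lines merge their flanking
blocks).  Conventions, fixed once:

* The genome listed first in a chain header is the lift-FROM (source)
  reference, matching UCSC liftOver chains, and per-line gap fields are
  (gap-in-source, gap-in-target).  Headers are validated against any
  supplied contig-length map; body spans must reproduce header spans
  exactly.
* All internal coordinates are 0-based half-open; SAM text is converted
  at I/O boundaries.  Reverse-strand target coordinates (counted on the
  reverse complement in the file) are converted to forward coordinates at
  parse time.
* The per-block offset is stored so that `target = source + offset` on
  `+` strands (and `target = offset − source` on `−`); the opposite sign
  convention would be equivalent, this one makes the common case an
  addition.

## Constant-time point lift

Index construction sorts the blocks of each source contig and marks their
start/end positions in two bit vectors of length contig+1.  Rank support
is a block directory: cumulative popcounts every 64 bits plus at most 8
byte-table lookups per query, so the per-query cost is independent of
both the position and the number of blocks (a unit test asserts the mean
query time varies by < 2× between indexes of 10² and 10⁴ intervals).
Coverage and block identity come from the two rank queries described in
the README.  Overlapping blocks from different chains are resolved
greedily by descending chain score — the higher-scoring chain keeps its
span, lower-scoring spans are trimmed to the free remainder (counts
logged); exact duplicate blocks are deduplicated with a warning.  The
index serializes to versioned JSON (chains only); bit vectors are rebuilt
deterministically on load, which a round-trip query-sweep test checks.

`allowed_gap` is the neighbor-snapping threshold for queries that fall
just outside every block: within that distance the query is assigned the
nearest block boundary's image.  No default is inherent to the method;
liftkit ships 0 (no snapping) and exposes it on the CLI.  A query
equidistant from two boundaries snaps to the left neighbor — an arbitrary
but fixed tie rule.

## CIGAR rewriting across gaps

`update_cigar_runs` walks the CIGAR runs and the chain's gap list once
(O(r+g)).  Invariants: I/S/H runs never touch gap arithmetic (they
consume no source reference); M/=/X bases paired with source-only gap
bases become I; crossing into the next block emits a D of the gap's
target-only length; D/N runs shrink by their overlap with source-only
gaps (N is treated as D for the arithmetic but re-emitted as N).
Normalization merges adjacent equal ops, folds edge insertions into soft
clips, and strips edge deletions; the lifted position is the image of the
first (on `−` strands, last) aligned base, so edge-deletion stripping
needs no separate position fix.  Query-consuming length is conserved
exactly — this is asserted on every synthetic run.

Reads that start inside a gap are admitted only if the unaligned prefix
is at most `allowed_gap` bases (the prefix becomes a soft clip);
likewise a read may overhang the final block of its chain by at most
`allowed_gap` soft-clipped bases.  Anything beyond is unliftable and
flows to the suppressed stream.  A read is lifted entirely within the
chain covering its leftmost base; alignments straddling two chains (e.g.
across an inversion breakpoint) are unliftable by design — they have no
single colinear image.

On `−` strands the sequence is reverse-complemented, qualities and CIGAR
reversed, and the reverse flags toggled; mate fields and TLEN are
refreshed per pair afterwards (signed outer distance, leftmost end
positive; proper-pair requires same contig and opposite orientations,
optionally an insert-size range).

## NM/MD and localized realignment

NM counts mismatches plus inserted plus deleted bases against the target
slice; MD follows the SAM convention; both are idempotent and recomputed
after every lift when the target genome is available (aligner-reported
tags refer to the source and would bias reconciliation).

Gap arithmetic preserves base pairing but not optimality — e.g. an
insertion emitted next to an existing deletion may cancel.  The optional
realignment runs an affine-gap DP (gap of length L costs open + L·extend)
of the read's aligned core against the lifted span padded by 20 bp per
side (clamped at contig ends): global in the query, free at both
reference ends.  The refined CIGAR is adopted only if it scores strictly
higher, making the operation idempotent.  Scoring presets named for
common aligners ship as YAML (bwa-mem 1/4/6/1, bowtie2 0/6/5/3, minimap2
2/4/4/2 for match/mismatch/open/extend).  Realignment is off by default.
The DP is exact; a from-scratch score-only DP in the test suite confirms
equality on hundreds of random reads.

## Selection policy

A record is suppressed if its lift failed or its source position overlaps
an annotated unliftable region; otherwise it is deferred if ANY enabled
feature fails — lifted into a mappability-reduced target region, MAPQ
below `mapq_min`, alignment score below `aln_score_min`, clipped fraction
above `clip_frac_max`, NM above `nm_max`, or fragment length outside
`frag_len_range`; otherwise committed.  The disjunctive reading of the
MAPQ-or-score rule is the conservative choice: a read failing either
signal is cheap to re-map and expensive to get wrong.  Shipped thresholds:
bwa-mem MAPQ 30 / AS 100 (local alignment), bowtie2 MAPQ 10 / AS −10
(end-to-end).  `clip_frac_max` defaults to 0.05; `nm_max` and
`frag_len_range` are disabled by default.  Classification is per-record
and order-independent, so partitioned processing reproduces the
single-stream assignment exactly.

## Liftability annotation

Unliftable regions: maximal source spans covered by no chain interval
and strictly longer than 5000 bp are extracted and placed on the target
with the pluggable mapper; spans with zero target loci (source-unique) or
two or more (repetitive) are labeled unliftable; single-locus spans lift
fine and are excluded.  Mapper failures conservatively label the span
unliftable.

Mappability of a position is 1/(number of positions whose k-mer is within
Hamming distance e of that position's k-mer, including itself), defaults
k = 100 and e = ⌈0.01·k⌉ = 1 — the 100-mer / 1 % mismatch convention;
substitution-only distance matches standard mappability tools.  The
computation is exact brute force, vectorized per diagonal offset with
cumulative mismatch sums (O(L²) overall), and is intended for desk-scale
genomes (≤ a few Mb); contigs are separated by never-matching sentinels
so windows cannot span contigs.  Mappability-reduced regions are the
lifted images of uniquely mappable source regions intersected with
target regions of mappability strictly below 0.5 (the threshold and the
strict inequality are package choices; both are configurable).  Reads
lifted there are deferred.

## Collate and reconcile

Collate streams deferred ends into two name-keyed hash maps (first/second
of pair), emits completed pairs immediately, then pulls the committed
mates of the remaining singletons so re-mapping runs in paired-end mode;
every deferred name ends up exactly 0 or 2 times in the paired-deferred
output.  Seeing the same name twice with the same pair flag is an error;
a mate found in neither stream passes through unpaired with a warning.

Reconcile compares candidates per (name, end), independently per end:
mapped beats unmapped (an unmapped record has no meaningful edit
distance); then lower NM (recomputed against the target when absent);
then higher MAPQ; then one pseudo-random draw seeded by
crc32(name/end) XOR seed, so the outcome is reproducible and independent
of processing order.  The final merge coordinate-sorts with the
deterministic key (contig, position, name, flag).

## Synthetic data generator

The generator edits a random uniform-ACGT base genome (target-like) into
a source genome while recording the exact base-level correspondence.
Edit classes and desk-scale default rates per bp: SNV 10⁻³, short
insertions/deletions 10⁻⁴ each (geometric lengths ≤ 20), inversions
2×10⁻⁵ (300–1500 bp), source-only segmental duplications 10⁻⁵
(1–4 kb, 2 % diverged copy — the target then looks falsely collapsed),
target-only duplications 10⁻⁵ (false duplication), novel source-only
segments 10⁻⁵ (5.5–9 kb, deliberately above the 5 kb unliftable filter;
a centromere stand-in).  These rates compress the structural-difference
density of real assembly pairs so that every event class appears in a
50–100 kb fixture; they are not estimates of any particular genome pair.
The correspondence map doubles as the lift oracle and serializes
losslessly to chain format (round-tripped in the tests).

The read simulator draws fragments uniformly (Normal(350, 35) insert,
100 bp ends, R1/R2 orientation swapped with probability ½) and applies
substitution errors at 0.002/bp by default.  Substitution-only errors
keep every read's true origin unambiguous, which is what the 10 bp
mapping-correctness rule needs; indel errors and non-uniform coverage
are deliberately not modeled.  Consequently the tests demonstrate
correctness of the lift/selection machinery, not robustness to real
sequencing artifacts.  A mapping is correct iff its leftmost aligned
base is within 10 bp of the origin on the same contig; unmapped or
missing reads are incorrect.  Multi-dataset F1 sums TP/FP/FN before
applying F1 = TP/(TP + 0.5(FP + FN)).

The built-in mapper (exact 21-mer seeds at five query offsets, full-length
Hamming verification, ≤ 10 % mismatches, concordance-aware pairing) stands
in for a production aligner at synthetic scale; indel-containing reads
and repeats beyond its seed scheme are out of its reach, which is
acceptable because deferred-read re-mapping quality is not the property
under test.  External aligners plug in via a command template (FASTQ in,
SAM on stdout).

## Problem sizes

Test and acceptance runs use genome fixtures of 8–200 kb, chain sets of
up to a few thousand intervals, and 10³–10⁴ reads or queries per
property — sizes chosen so the full suite and the acceptance script each
complete in minutes on one core while still exercising every code path
(dense gap structures, inversions, duplications, all selection reasons).

## Known limitations

* One lift per primary record: SA-tag rewriting for supplementary
  alignments and MC (mate CIGAR) maintenance are out of scope (logged).
* Reads spanning two chains (inversion breakpoints, trimmed overlaps)
  are unliftable rather than split.
* The brute-force mappability and naive mapper do not scale past a few
  Mb; both are pluggable boundaries for production tools.
* Base-quality recalibration, spliced alignment semantics (N is carried
  through but not interpreted), and duplicate marking are not handled.
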