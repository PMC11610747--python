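"""Build the genomic liftability annotation.

Two kinds of regions are produced:

* **unliftable** (source coordinates): maximal source spans covered by no
  chain interval and longer than 5000 bp are extracted and placed on the
  target with a mapper; spans that are unmapped or map to multiple target
  loci are labeled unliftable.  Reads mapped there are suppressed.
* **mappability_reduced** (target coordinates): positions uniquely
  mappable in the source whose lifted image falls in a low-mappability
  target region.  Reads lifted there are deferred and re-mapped.

Mappability of a position is the reciprocal of the number of positions in
the genome whose k-mer lies within Hamming distance e of that position's
k-mer (including itself); the defaults k=100, e=ceil(0.01*k)=1 follow the
100-mer / 1% mismatch-rate convention.  The computation here is an exact
brute-force routine intended for desk-scale (<= a few Mb) genomes.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable

import numpy as np

from .chain import ChainIndex
from .mapper import Mapper
from .selector import MAPPABILITY_REDUCED, UNLIFTABLE, LiftabilityAnnotation

logger = logging.getLogger(__name__)

DEFAULT_K = 100
DEFAULT_MISMATCH_RATE = 0.01
MIN_UNLIFTABLE_SEGMENT = 5000


def mismatch_tolerance(k: int, rate: float = DEFAULT_MISMATCH_RATE) -> int:
    """Tolerated mismatches e = ceil(rate * k)."""
    return math.ceil(rate * k)


class MappabilityTrack:
    """Per-position mappability in (0, 1] for each contig.

    Values are defined for positions with a full k-mer (the last k-1
    positions of each contig carry no value).
    """

    def __init__(self, values: dict[str, np.ndarray], k: int, e: int):
        self.values = values
        self.k = k
        self.e = e

    def regions_where(self, predicate) -> list[tuple[str, int, int]]:
        """Maximal runs of k-mer start positions whose value satisfies predicate."""
        out = []
        for contig in sorted(self.values):
            vals = self.values[contig]
            mask = predicate(vals)
            if not mask.any():
                continue
            d = np.diff(mask.astype(np.int8))
            starts = list(np.where(d == 1)[0] + 1)
            ends = list(np.where(d == -1)[0] + 1)
            if mask[0]:
                starts.insert(0, 0)
            if mask[-1]:
                ends.append(len(mask))
            out.extend((contig, int(s), int(e)) for s, e in zip(starts, ends))
        return out

    def unique_regions(self) -> list[tuple[str, int, int]]:
        return self.regions_where(lambda v: v >= 1.0)

    def low_regions(self, threshold: float) -> list[tuple[str, int, int]]:
        return self.regions_where(lambda v: v < threshold)

    def to_bedgraph(self, path: str) -> None:
        with open(path, "w") as fh:
            for contig in sorted(self.values):
                vals = self.values[contig]
                i = 0
                while i < len(vals):
                    j = i
                    while j < len(vals) and vals[j] == vals[i]:
                        j += 1
                    fh.write(f"{contig}\t{i}\t{j}\t{vals[i]:.6g}\n")
                    i = j


def compute_mappability(genome: dict[str, str], k: int = DEFAULT_K,
                        e: int | None = None) -> MappabilityTrack:
    """Exact k-mer mappability with up to e substitutions, by brute force.

    For every pair of k-mer positions (across all contigs, forward strand)
    the Hamming distance is evaluated via per-offset cumulative mismatch
    sums — O(L^2) overall but fully vectorized.  Contigs shorter than k
    yield an empty track.
    """
    if e is None:
        e = mismatch_tolerance(k)
    names = sorted(genome)
    # concatenate with k 0-sentinels between contigs so windows never span two
    parts = []
    offsets = {}
    cursor = 0
    sep = np.zeros(k, dtype=np.uint8)
    for name in names:
        seq = genome[name].upper()
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        if parts:
            parts.append(sep)
            cursor += k
        offsets[name] = cursor
        parts.append(arr)
        cursor += len(arr)
    if not parts:
        return MappabilityTrack({}, k, e)
    cat = np.concatenate(parts)
    L = len(cat)
    valid = np.zeros(L, dtype=bool)
    for name in names:
        n = len(genome[name])
        if n >= k:
            valid[offsets[name]: offsets[name] + n - k + 1] = True
    counts = np.zeros(L, dtype=np.int64)
    counts[valid] = 1  # self-match
    nz = ~np.equal(cat, 0)
    for d in range(1, L):
        neq = (cat[d:] != cat[:-d]) | ~nz[d:] | ~nz[:-d]
        if len(neq) < k:
            break
        # sliding window of length k via cumulative sum
        cs = np.concatenate([[0], np.cumsum(neq, dtype=np.int64)])
        win = cs[k:] - cs[:-k]
        ok = win <= e
        idx = np.where(ok)[0]
        if idx.size:
            lo = valid[idx] & valid[idx + d]
            idx = idx[lo]
            counts[idx] += 1
            counts[idx + d] += 1
    values = {}
    for name in names:
        n = len(genome[name])
        if n < k:
            values[name] = np.zeros(0, dtype=np.float64)
            continue
        c = counts[offsets[name]: offsets[name] + n - k + 1]
        values[name] = 1.0 / c
    return MappabilityTrack(values, k, e)


def extract_nonchain_segments(source_lengths: dict[str, int], idx: ChainIndex,
                              min_len: int = MIN_UNLIFTABLE_SEGMENT
                              ) -> list[tuple[str, int, int]]:
    """Maximal source spans covered by no chain interval and longer than min_len."""
    out = []
    for contig in sorted(source_lengths):
        length = source_lengths[contig]
        covered = (idx.covered_spans(contig)
                   if contig in idx.source_contigs else [])
        cursor = 0
        for s, e in covered + [(length, length)]:
            if s - cursor > min_len:
                out.append((contig, cursor, s))
            cursor = max(cursor, e)
    return out


def label_unliftable(segments: Iterable[tuple[str, int, int]],
                     source_genome: dict[str, str],
                     mapper: Mapper) -> list[tuple[str, int, int]]:
    """Keep segments that are unmapped or repetitive on the target.

    A segment with exactly one target locus lifts cleanly and is excluded;
    zero loci (source-unique) or two-plus loci (repetitive) are unliftable.
    A mapper failure conservatively labels the segment unliftable.
    """
    out = []
    for contig, start, end in segments:
        seq = source_genome[contig][start:end]
        try:
            n = (mapper.count_loci(seq) if hasattr(mapper, "count_loci")
                 else len(mapper.map_sequence(seq)))
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("mapper failed on %s:%d-%d (%s); labeling unliftable",
                           contig, start, end, exc)
            n = 0
        if n != 1:
            out.append((contig, start, end))
    return out


def _intersect(a: list[tuple[str, int, int]], b: list[tuple[str, int, int]]):
    from collections import defaultdict
    by_contig = defaultdict(list)
    for contig, s, e in b:
        by_contig[contig].append((s, e))
    out = []
    for contig, s, e in a:
        for bs, be in by_contig.get(contig, ()):
            lo, hi = max(s, bs), min(e, be)
            if lo < hi:
                out.append((contig, lo, hi))
    out.sort()
    return out


def lift_region(idx: ChainIndex, contig: str, start: int, end: int
                ) -> list[tuple[str, int, int]]:
    """Lift a source region piecewise through the chain intervals."""
    if contig not in idx.source_contigs:
        return []
    out = []
    ci = idx._contigs[contig]
    for piece in ci.pieces:
        lo, hi = max(start, piece.source_start), min(end, piece.source_end)
        if lo >= hi:
            continue
        t1, t2 = piece.lift(lo), piece.lift(hi - 1)
        out.append((piece.target_contig, min(t1, t2), max(t1, t2) + 1))
    out.sort()
    return out


def build_mappability_reduced(source_track: MappabilityTrack,
                              target_track: MappabilityTrack,
                              idx: ChainIndex,
                              unique_threshold: float = 1.0,
                              low_threshold: float = 0.5
                              ) -> list[tuple[str, int, int]]:
    """Target regions where uniquely-mappable source sequence lands in
    low-mappability target sequence.

    Source regions with mappability == ``unique_threshold`` are lifted and
    intersected with target regions of mappability strictly below
    ``low_threshold``.  Unliftable unique regions are skipped (counted in
    the log).
    """
    if (source_track.k, source_track.e) != (target_track.k, target_track.e):
        raise ValueError("source and target tracks use different (k, e)")
    unique = source_track.regions_where(lambda v: v >= unique_threshold)
    lifted = []
    n_skipped = 0
    for contig, s, e in unique:
        imgs = lift_region(idx, contig, s, e)
        if not imgs:
            n_skipped += 1
        lifted.extend(imgs)
    if n_skipped:
        logger.info("%d uniquely-mappable source regions had no lifted image",
                    n_skipped)
    low = target_track.low_regions(low_threshold)
    return _intersect(lifted, low)


def build_annotation(source_genome: dict[str, str],
                     target_genome: dict[str, str],
                     idx: ChainIndex,
                     mapper: Mapper | None = None,
                     k: int = DEFAULT_K,
                     e: int | None = None,
                     min_segment: int = MIN_UNLIFTABLE_SEGMENT,
                     low_threshold: float = 0.5) -> LiftabilityAnnotation:
    """Full annotation pass: unliftable + mappability-reduced regions."""
    from .mapper import NaiveMapper
    if mapper is None:
        mapper = NaiveMapper(target_genome)
    lengths = {name: len(seq) for name, seq in source_genome.items()}
    segments = extract_nonchain_segments(lengths, idx, min_len=min_segment)
    unliftable = label_unliftable(segments, source_genome, mapper)
    src_track = compute_mappability(source_genome, k=k, e=e)
    tgt_track = compute_mappability(target_genome, k=k, e=e)
    reduced = build_mappability_reduced(src_track, tgt_track, idx,
                                        low_threshold=low_threshold)
    ann = LiftabilityAnnotation()
    for contig, s, e_ in unliftable:
        ann.add(contig, s, e_, UNLIFTABLE)
    for contig, s, e_ in reduced:
        ann.add(contig, s, e_, MAPPABILITY_REDUCED)
    return ann
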