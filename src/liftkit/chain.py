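"""Chain-file parsing and constant-time coordinate lift-over.

A UCSC chain file describes a pairwise whole-genome alignment as a set of
"chains": co-linear runs of gapless aligned blocks separated by gaps in
either genome.  This module parses chains into :class:`ChainInterval` /
:class:`ChainGap` structures, builds a :class:`ChainIndex` that answers
point lift queries in constant time using a pair of rank-supported bit
vectors (``start_bv`` marks interval starts, ``end_bv`` marks interval
ends), and supports inversion (target->source) and lossless JSON
serialization.

Conventions
-----------
* The genome listed first in a chain header is the lift-FROM (source)
  reference, as in UCSC liftOver chains; per-line gap fields are
  (gap-in-source, gap-in-target).
* All internal coordinates are 0-based half-open.  '-'-strand target
  coordinates (counted on the reverse complement in the chain file) are
  converted to forward-strand coordinates at parse time.
* Interval offsets satisfy ``target = source + offset`` on '+' strands and
  ``target = offset - source`` on '-' strands (offset = target_end - 1 +
  source_start), so a single signed integer describes either direction.
"""

from __future__ import annotations

import gzip
import io
import json
import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

INDEX_FORMAT_VERSION = 1


class ChainError(ValueError):
    """Base class for chain parsing/validation problems."""


class ChainParseError(ChainError):
    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ChainValidationError(ChainError):
    pass


# ---------------------------------------------------------------------------
# Rank bit vector
# ---------------------------------------------------------------------------

_POPCOUNT8 = np.unpackbits(
    np.arange(256, dtype=np.uint8)[:, None], axis=1
).sum(axis=1).astype(np.int64)


class RankBitVector:
    """Bit vector with a block rank directory giving O(1) rank queries.

    ``rank(p)`` counts set bits at indices strictly below ``p``.  The rank
    directory stores cumulative popcounts every 8 bytes, so a query touches
    at most 8 table lookups regardless of vector length or density.
    """

    BLOCK_BYTES = 8

    def __init__(self, length: int, set_positions: Iterable[int] = ()):
        self.length = int(length)
        if self.length < 0:
            raise ValueError("length must be non-negative")
        pos = np.unique(np.fromiter((int(p) for p in set_positions), dtype=np.int64))
        if pos.size and (pos[0] < 0 or pos[-1] >= self.length):
            raise ValueError("set position out of range")
        self._positions = pos
        bits = np.zeros(self.length, dtype=np.uint8)
        if pos.size:
            bits[pos] = 1
        self._bytes = np.packbits(bits)
        nbytes = self._bytes.size
        pad = (-nbytes) % self.BLOCK_BYTES
        counts = _POPCOUNT8[np.concatenate([self._bytes, np.zeros(pad, dtype=np.uint8)])]
        block_sums = counts.reshape(-1, self.BLOCK_BYTES).sum(axis=1)
        self._block_rank = np.concatenate([[0], np.cumsum(block_sums)])

    @property
    def count(self) -> int:
        """Total number of set bits."""
        return int(self._block_rank[-1])

    @property
    def positions(self) -> np.ndarray:
        return self._positions

    def __getitem__(self, i: int) -> int:
        if not 0 <= i < self.length:
            raise IndexError(i)
        return (self._bytes[i >> 3] >> (7 - (i & 7))) & 1

    def rank(self, p: int) -> int:
        """Number of set bits at indices < p (0 <= p <= length)."""
        if not 0 <= p <= self.length:
            raise ValueError(f"rank position {p} out of range [0, {self.length}]")
        nbyte, rem = divmod(p, 8)
        blk, brem = divmod(nbyte, self.BLOCK_BYTES)
        r = int(self._block_rank[blk])
        base = blk * self.BLOCK_BYTES
        for b in self._bytes[base: base + brem]:
            r += int(_POPCOUNT8[b])
        if rem and nbyte < self._bytes.size:
            r += int(_POPCOUNT8[self._bytes[nbyte] >> (8 - rem)])
        return r


# ---------------------------------------------------------------------------
# Chain model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChainInterval:
    """One gapless aligned block: source span <-> target span (forward coords)."""

    source_contig: str
    source_start: int
    source_end: int
    target_contig: str
    target_start: int
    target_end: int
    strand: str  # strand of target relative to source: '+' or '-'
    chain_id: int = 0

    def __post_init__(self):
        if self.source_start >= self.source_end:
            raise ChainValidationError(
                f"empty interval [{self.source_start},{self.source_end})")
        if self.source_end - self.source_start != self.target_end - self.target_start:
            raise ChainValidationError("source and target spans differ in length")
        if self.strand not in "+-":
            raise ChainValidationError(f"bad strand {self.strand!r}")

    @property
    def offset(self) -> int:
        """target = source + offset ('+') or target = offset - source ('-')."""
        if self.strand == "+":
            return self.target_start - self.source_start
        return self.target_end - 1 + self.source_start

    def lift(self, p: int) -> int:
        """Map a covered source position to its forward-strand target position."""
        if not self.source_start <= p < self.source_end:
            raise ValueError(f"{p} not in [{self.source_start},{self.source_end})")
        if self.strand == "+":
            return p + (self.target_start - self.source_start)
        return self.target_end - 1 - (p - self.source_start)

    def contains(self, p: int) -> bool:
        return self.source_start <= p < self.source_end


@dataclass(frozen=True)
class ChainGap:
    """Gap after an aligned block within a chain.

    ``source_break`` is the source position where the preceding block ends;
    ``dsource`` bases of source-only sequence and ``dtarget`` bases of
    target-only sequence separate it from the next block.
    """

    source_break: int
    dsource: int
    dtarget: int

    def __post_init__(self):
        if self.dsource < 0 or self.dtarget < 0:
            raise ChainValidationError("negative gap length")


@dataclass
class Chain:
    """One chain: header metadata plus ordered intervals and gaps."""

    chain_id: int
    score: int
    source_contig: str
    source_size: int
    source_start: int
    source_end: int
    target_contig: str
    target_size: int
    strand: str
    target_start: int  # forward coords of the chain's target span
    target_end: int
    intervals: list[ChainInterval] = field(default_factory=list)
    gaps: list[ChainGap] = field(default_factory=list)

    def interval_covering(self, p: int) -> ChainInterval | None:
        i = bisect_right([iv.source_start for iv in self.intervals], p) - 1
        if i >= 0 and self.intervals[i].contains(p):
            return self.intervals[i]
        return None

    def lift(self, p: int) -> int | None:
        iv = self.interval_covering(p)
        return None if iv is None else iv.lift(p)

    @property
    def last_source_end(self) -> int:
        return self.intervals[-1].source_end


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


def _open_maybe_gzip(path_or_stream):
    if hasattr(path_or_stream, "read"):
        return path_or_stream, False
    path = str(path_or_stream)
    if path.endswith(".gz"):
        return gzip.open(path, "rt"), True
    return open(path, "rt"), True


def parse_chain(
    chain_input,
    source_contig_lengths: dict[str, int] | None = None,
) -> list[Chain]:
    """Parse a chain file (path, text, or stream) into :class:`Chain` objects.

    Aligned blocks may contain matches and mismatches but no gaps; each data
    line yields one interval and at most one gap.  '-'-strand target
    coordinates are converted to forward coordinates here.  Zero-length gaps
    (dsource = dtarget = 0) merge their flanking blocks.

    Parameters
    ----------
    chain_input:
        Path to a chain file (plain or gzip), a text stream, or raw chain
        text containing at least one "chain" header line.
    source_contig_lengths:
        Optional map of source contig -> length used to validate headers.
    """
    if isinstance(chain_input, str) and "\n" in chain_input:
        stream, close = io.StringIO(chain_input), False
    else:
        stream, close = _open_maybe_gzip(chain_input)

    chains: list[Chain] = []
    cur: Chain | None = None
    src_cursor = tgt_cursor = 0  # tgt_cursor runs in strand coords
    auto_id = 0
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                if cur is not None and not cur.intervals:
                    raise ChainParseError("chain header with no data lines", lineno)
                if cur is not None:
                    raise ChainParseError("blank line inside chain body", lineno)
                continue
            fields = line.split()
            if fields[0] == "chain":
                if cur is not None:
                    raise ChainParseError("chain header before previous chain ended", lineno)
                if len(fields) not in (12, 13):
                    raise ChainParseError(f"chain header has {len(fields)} fields", lineno)
                try:
                    score = int(float(fields[1]))
                    s_name, s_size, s_strand = fields[2], int(fields[3]), fields[4]
                    s_start, s_end = int(fields[5]), int(fields[6])
                    t_name, t_size, t_strand = fields[7], int(fields[8]), fields[9]
                    t_start, t_end = int(fields[10]), int(fields[11])
                except ValueError as exc:
                    raise ChainParseError(f"malformed header: {exc}", lineno) from None
                chain_id = int(fields[12]) if len(fields) == 13 else auto_id
                auto_id = max(auto_id, chain_id) + 1
                if s_strand != "+":
                    raise ChainParseError("source strand must be '+'", lineno)
                if t_strand not in "+-":
                    raise ChainParseError(f"bad target strand {t_strand!r}", lineno)
                if not (0 <= s_start < s_end <= s_size):
                    raise ChainValidationError(
                        f"line {lineno}: source span [{s_start},{s_end}) "
                        f"outside contig of size {s_size}")
                if not (0 <= t_start < t_end <= t_size):
                    raise ChainValidationError(
                        f"line {lineno}: target span outside contig")
                if source_contig_lengths is not None:
                    if s_name not in source_contig_lengths:
                        raise ChainValidationError(
                            f"line {lineno}: contig {s_name!r} absent from lengths map")
                    if source_contig_lengths[s_name] != s_size:
                        raise ChainValidationError(
                            f"line {lineno}: contig {s_name!r} size {s_size} != "
                            f"{source_contig_lengths[s_name]}")
                if t_strand == "+":
                    fwd_start, fwd_end = t_start, t_end
                else:
                    fwd_start, fwd_end = t_size - t_end, t_size - t_start
                cur = Chain(
                    chain_id=chain_id, score=score,
                    source_contig=s_name, source_size=s_size,
                    source_start=s_start, source_end=s_end,
                    target_contig=t_name, target_size=t_size, strand=t_strand,
                    target_start=fwd_start, target_end=fwd_end,
                )
                src_cursor, tgt_cursor = s_start, t_start
                continue
            if cur is None:
                raise ChainParseError("data line outside any chain", lineno)
            if len(fields) not in (1, 3):
                raise ChainParseError(f"data line has {len(fields)} fields", lineno)
            try:
                size = int(fields[0])
                dsource = int(fields[1]) if len(fields) == 3 else 0
                dtarget = int(fields[2]) if len(fields) == 3 else 0
            except ValueError as exc:
                raise ChainParseError(f"malformed data line: {exc}", lineno) from None
            if size <= 0:
                raise ChainParseError("block size must be positive", lineno)
            if cur.strand == "+":
                t_fwd_lo = tgt_cursor
            else:
                t_fwd_lo = cur.target_size - (tgt_cursor + size)
            prev = cur.intervals[-1] if cur.intervals else None
            merged = (
                prev is not None
                and cur.gaps
                and cur.gaps[-1].dsource == 0 and cur.gaps[-1].dtarget == 0
            )
            if merged:
                cur.gaps.pop()
                cur.intervals[-1] = ChainInterval(
                    prev.source_contig, prev.source_start, src_cursor + size,
                    prev.target_contig,
                    min(prev.target_start, t_fwd_lo),
                    max(prev.target_end, t_fwd_lo + size),
                    prev.strand, prev.chain_id)
            else:
                cur.intervals.append(ChainInterval(
                    cur.source_contig, src_cursor, src_cursor + size,
                    cur.target_contig, t_fwd_lo, t_fwd_lo + size,
                    cur.strand, cur.chain_id))
            src_cursor += size
            tgt_cursor += size
            if len(fields) == 3:
                cur.gaps.append(ChainGap(src_cursor, dsource, dtarget))
                src_cursor += dsource
                tgt_cursor += dtarget
            else:
                # terminal line: chain body ends here
                if src_cursor != cur.source_end:
                    raise ChainValidationError(
                        f"line {lineno}: chain {cur.chain_id} body spans "
                        f"{src_cursor - cur.source_start} source bp, header "
                        f"says {cur.source_end - cur.source_start}")
                t_span = tgt_cursor - (
                    cur.target_start if cur.strand == "+"
                    else cur.target_size - cur.target_end)
                if t_span != cur.target_end - cur.target_start:
                    raise ChainValidationError(
                        f"line {lineno}: chain {cur.chain_id} body spans "
                        f"{t_span} target bp, header says "
                        f"{cur.target_end - cur.target_start}")
                if src_cursor > cur.source_end:
                    raise ChainValidationError(
                        f"line {lineno}: body exceeds header source span")
                chains.append(cur)
                cur = None
        if cur is not None:
            raise ChainParseError("chain body not terminated by a bare size line")
    finally:
        if close:
            stream.close()
    return chains


# ---------------------------------------------------------------------------
# Index
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LiftedPoint:
    target_contig: str
    target_pos: int
    strand: str
    chain_id: int
    interval: ChainInterval
    snap_distance: int = 0

    def __bool__(self) -> bool:
        return True


@dataclass(frozen=True)
class Unliftable:
    reason: str

    def __bool__(self) -> bool:
        return False


@dataclass
class _ContigIndex:
    starts: np.ndarray
    ends: np.ndarray
    pieces: list[ChainInterval]
    start_bv: RankBitVector
    end_bv: RankBitVector


class ChainIndex:
    """Queryable lift-over index over a set of chains for one source genome.

    Per source contig the index keeps a sorted, non-overlapping array of
    (possibly trimmed) chain intervals plus the paired ``start_bv``/``end_bv``
    rank bit vectors.  A point query does two rank queries: the position is
    covered iff ``rank(start_bv, p+1) - rank(end_bv, p+1) == 1``, and the
    covering interval's array index is ``rank(start_bv, p+1) - 1``.

    ``allowed_gap`` is the neighbor-snapping threshold: a query falling
    outside all intervals but within ``allowed_gap`` of an interval boundary
    is assigned to that neighbor (ties snap to the left neighbor).
    """

    def __init__(self, chains: Sequence[Chain], allowed_gap: int = 0,
                 source_contig_lengths: dict[str, int] | None = None):
        self.allowed_gap = int(allowed_gap)
        self.chains: dict[int, Chain] = {}
        self.source_lengths: dict[str, int] = dict(source_contig_lengths or {})
        self.target_lengths: dict[str, int] = {}
        self._contigs: dict[str, _ContigIndex] = {}
        self.n_dropped_overlap = 0
        self.n_deduplicated = 0
        self._build(list(chains))

    # -- construction -----------------------------------------------------

    def _build(self, chains: list[Chain]) -> None:
        for ch in chains:
            if ch.chain_id in self.chains:
                raise ChainValidationError(f"duplicate chain id {ch.chain_id}")
            self.chains[ch.chain_id] = ch
            known = self.source_lengths.get(ch.source_contig)
            if known is not None and known != ch.source_size:
                raise ChainValidationError(
                    f"contig {ch.source_contig!r}: header size {ch.source_size} "
                    f"!= known length {known}")
            self.source_lengths[ch.source_contig] = ch.source_size
            self.target_lengths[ch.target_contig] = ch.target_size

        by_contig: dict[str, list[tuple[int, ChainInterval]]] = {}
        for ch in sorted(chains, key=lambda c: -c.score):
            for iv in ch.intervals:
                by_contig.setdefault(iv.source_contig, []).append((ch.score, iv))

        for contig, length in self.source_lengths.items():
            scored = by_contig.get(contig, [])
            pieces = self._resolve_overlaps(scored)
            starts = np.array([p.source_start for p in pieces], dtype=np.int64)
            ends = np.array([p.source_end for p in pieces], dtype=np.int64)
            self._contigs[contig] = _ContigIndex(
                starts=starts, ends=ends, pieces=pieces,
                start_bv=RankBitVector(length + 1, starts),
                end_bv=RankBitVector(length + 1, ends),
            )

    def _resolve_overlaps(
        self, scored: list[tuple[int, ChainInterval]]
    ) -> list[ChainInterval]:
        """Greedy claim by descending chain score; lower-score spans trimmed."""
        claimed: list[tuple[int, int]] = []  # sorted disjoint (start, end)
        pieces: list[ChainInterval] = []
        seen: set[tuple] = set()
        for score, iv in scored:
            key = (iv.source_start, iv.source_end, iv.target_contig,
                   iv.target_start, iv.strand)
            if key in seen:
                self.n_deduplicated += 1
                logger.warning("duplicate interval %s deduplicated", key)
                continue
            seen.add(key)
            free = self._free_subspans(claimed, iv.source_start, iv.source_end)
            if sum(hi - lo for lo, hi in free) < iv.source_end - iv.source_start:
                self.n_dropped_overlap += 1
            for lo, hi in free:
                if iv.strand == "+":
                    t_lo = iv.target_start + (lo - iv.source_start)
                    t_hi = t_lo + (hi - lo)
                else:
                    t_hi = iv.target_end - (lo - iv.source_start)
                    t_lo = t_hi - (hi - lo)
                pieces.append(ChainInterval(
                    iv.source_contig, lo, hi, iv.target_contig,
                    t_lo, t_hi, iv.strand, iv.chain_id))
                self._claim(claimed, lo, hi)
        pieces.sort(key=lambda p: p.source_start)
        if self.n_dropped_overlap:
            logger.warning("%d interval spans trimmed or dropped due to "
                           "overlap between chains", self.n_dropped_overlap)
        return pieces

    @staticmethod
    def _free_subspans(claimed: list[tuple[int, int]], lo: int, hi: int):
        """Subspans of [lo, hi) not covered by the claimed list."""
        out = []
        i = bisect_right(claimed, (lo, float("inf"))) - 1
        cur = lo
        if i >= 0 and claimed[i][1] > lo:
            cur = max(cur, claimed[i][1])
        i += 1
        while cur < hi:
            if i < len(claimed) and claimed[i][0] < hi:
                if claimed[i][0] > cur:
                    out.append((cur, claimed[i][0]))
                cur = max(cur, claimed[i][1])
                i += 1
            else:
                out.append((cur, hi))
                cur = hi
        return out

    @staticmethod
    def _claim(claimed: list[tuple[int, int]], lo: int, hi: int) -> None:
        i = bisect_left(claimed, (lo, hi))
        claimed.insert(i, (lo, hi))
        # merge neighbors to keep the list small
        merged: list[tuple[int, int]] = []
        for span in claimed:
            if merged and span[0] <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], span[1]))
            else:
                merged.append(span)
        claimed[:] = merged

    # -- queries ----------------------------------------------------------

    @property
    def source_contigs(self) -> list[str]:
        return list(self._contigs)

    def num_intervals(self, contig: str) -> int:
        return len(self._contigs[contig].pieces)

    def rank_pair(self, contig: str, p: int) -> tuple[int, int]:
        """(rank(start_bv, p), rank(end_bv, p)) for diagnostics/tests."""
        ci = self._contigs[contig]
        return ci.start_bv.rank(p), ci.end_bv.rank(p)

    def is_covered(self, contig: str, p: int) -> bool:
        ci = self._contigs.get(contig)
        if ci is None or p < 0 or p >= ci.start_bv.length - 1:
            return False
        return ci.start_bv.rank(p + 1) - ci.end_bv.rank(p + 1) == 1

    def lift_position(self, contig: str, p: int) -> LiftedPoint | Unliftable:
        """Lift one source position; O(1) per query.

        Covered positions map through their interval.  Uncovered positions
        within ``allowed_gap`` of a neighboring interval boundary are snapped
        to that boundary's image; anything else is unliftable.
        """
        ci = self._contigs.get(contig)
        if ci is None:
            return Unliftable("unknown_contig")
        if p < 0 or p >= self.source_lengths[contig]:
            return Unliftable("position_out_of_range")
        i_start = ci.start_bv.rank(p + 1)
        i_end = ci.end_bv.rank(p + 1)
        if i_start - i_end == 1:
            piece = ci.pieces[i_start - 1]
            return LiftedPoint(piece.target_contig, piece.lift(p), piece.strand,
                               piece.chain_id, piece)
        # uncovered: i_start == i_end == number of pieces entirely left of p
        if self.allowed_gap <= 0:
            return Unliftable("no_covering_interval")
        d_left = d_right = None
        if i_end >= 1:
            d_left = p - (int(ci.ends[i_end - 1]) - 1)
        if i_start < len(ci.pieces):
            d_right = int(ci.starts[i_start]) - p
        best = None
        if d_left is not None and d_left <= self.allowed_gap:
            piece = ci.pieces[i_end - 1]
            best = LiftedPoint(piece.target_contig, piece.lift(piece.source_end - 1),
                               piece.strand, piece.chain_id, piece, d_left)
        if d_right is not None and d_right <= self.allowed_gap:
            if best is None or d_right < best.snap_distance:
                piece = ci.pieces[i_start]
                best = LiftedPoint(piece.target_contig, piece.lift(piece.source_start),
                                   piece.strand, piece.chain_id, piece, d_right)
        return best if best is not None else Unliftable("no_covering_interval")

    def covered_spans(self, contig: str) -> list[tuple[int, int]]:
        """Maximal merged source spans covered by any interval."""
        ci = self._contigs[contig]
        spans: list[tuple[int, int]] = []
        for p in ci.pieces:
            if spans and p.source_start <= spans[-1][1]:
                spans[-1] = (spans[-1][0], max(spans[-1][1], p.source_end))
            else:
                spans.append((p.source_start, p.source_end))
        return spans

    # -- inversion --------------------------------------------------------

    def invert(self) -> "ChainIndex":
        """Build the target->source index (swaps the roles of the genomes)."""
        inv_chains = []
        for ch in self.chains.values():
            ivs = [ChainInterval(iv.target_contig, iv.target_start, iv.target_end,
                                 iv.source_contig, iv.source_start, iv.source_end,
                                 iv.strand, iv.chain_id)
                   for iv in ch.intervals]
            ivs.sort(key=lambda iv: iv.source_start)
            gaps = []
            for a, b in zip(ivs, ivs[1:]):
                ds = b.source_start - a.source_end
                if ch.strand == "+":
                    dt = b.target_start - a.target_end
                else:
                    dt = a.target_start - b.target_end
                gaps.append(ChainGap(a.source_end, ds, dt))
            inv_chains.append(Chain(
                chain_id=ch.chain_id, score=ch.score,
                source_contig=ch.target_contig, source_size=ch.target_size,
                source_start=ivs[0].source_start, source_end=ivs[-1].source_end,
                target_contig=ch.source_contig, target_size=ch.source_size,
                strand=ch.strand,
                target_start=ch.source_start, target_end=ch.source_end,
                intervals=ivs, gaps=gaps))
        return ChainIndex(inv_chains, allowed_gap=self.allowed_gap)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "liftkit-chain-index",
            "version": INDEX_FORMAT_VERSION,
            "allowed_gap": self.allowed_gap,
            "source_lengths": self.source_lengths,
            "chains": [
                {
                    "chain_id": ch.chain_id, "score": ch.score,
                    "source_contig": ch.source_contig, "source_size": ch.source_size,
                    "source_start": ch.source_start, "source_end": ch.source_end,
                    "target_contig": ch.target_contig, "target_size": ch.target_size,
                    "strand": ch.strand,
                    "target_start": ch.target_start, "target_end": ch.target_end,
                    "intervals": [
                        [iv.source_start, iv.source_end, iv.target_start, iv.target_end]
                        for iv in ch.intervals],
                    "gaps": [[g.source_break, g.dsource, g.dtarget] for g in ch.gaps],
                }
                for ch in self.chains.values()
            ],
        }

    def save(self, path: str) -> None:
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "ChainIndex":
        if d.get("format") != "liftkit-chain-index":
            raise ChainValidationError("not a liftkit chain index")
        if d.get("version") != INDEX_FORMAT_VERSION:
            raise ChainValidationError(f"unsupported index version {d.get('version')}")
        chains = []
        for cd in d["chains"]:
            ivs = [ChainInterval(cd["source_contig"], s, e, cd["target_contig"],
                                 ts, te, cd["strand"], cd["chain_id"])
                   for s, e, ts, te in cd["intervals"]]
            gaps = [ChainGap(*g) for g in cd["gaps"]]
            chains.append(Chain(
                chain_id=cd["chain_id"], score=cd["score"],
                source_contig=cd["source_contig"], source_size=cd["source_size"],
                source_start=cd["source_start"], source_end=cd["source_end"],
                target_contig=cd["target_contig"], target_size=cd["target_size"],
                strand=cd["strand"],
                target_start=cd["target_start"], target_end=cd["target_end"],
                intervals=ivs, gaps=gaps))
        return cls(chains, allowed_gap=d["allowed_gap"],
                   source_contig_lengths={k: int(v) for k, v in d["source_lengths"].items()})

    @classmethod
    def load(cls, path: str) -> "ChainIndex":
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            return cls.from_dict(json.load(fh))


def build_index(chains: Sequence[Chain], allowed_gap: int = 0,
                source_contig_lengths: dict[str, int] | None = None) -> ChainIndex:
    """Build a :class:`ChainIndex` from parsed chains."""
    return ChainIndex(chains, allowed_gap=allowed_gap,
                      source_contig_lengths=source_contig_lengths)
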