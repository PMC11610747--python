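"""Pluggable read/segment mapping interface with a built-in naive mapper.

The lift-over workflow needs a mapper twice: to re-map deferred reads to
the target genome, and to place extracted source-unique segments on the
target when building the liftability annotation.  Production pipelines
plug in an external aligner through :class:`ExternalMapper` (a command
template that reads FASTQ and writes SAM on stdout).  For synthetic-scale
genomes the built-in :class:`NaiveMapper` — exact k-mer seeding plus
full-length Hamming verification — is adequate and dependency-free.
"""

from __future__ import annotations

import logging
import shlex
import subprocess
from dataclasses import dataclass
from typing import Iterable, Protocol, Sequence

import pysam

from .engine import reverse_complement

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Hit:
    contig: str
    pos: int
    strand: str  # '+' or '-'
    nm: int      # Hamming distance over the full query


class Mapper(Protocol):
    def map_sequence(self, seq: str) -> list[Hit]:
        """All plausible loci for a sequence, best (lowest nm) first."""
        ...


class NaiveMapper:
    """Exact-seed + Hamming-verify mapper for desk-scale genomes.

    Seeds of length ``k`` taken at a few query offsets vote for candidate
    diagonals; each candidate is verified by a full-length Hamming
    comparison and kept if within ``max_mismatch_frac`` of the query
    length.  Only substitutions are modeled, which matches the synthetic
    read simulator.
    """

    def __init__(self, genome: dict[str, str], k: int = 21,
                 max_mismatch_frac: float = 0.1):
        self.genome = {name: seq.upper() for name, seq in genome.items()}
        self.k = k
        self.max_mismatch_frac = max_mismatch_frac
        self._index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.genome.items():
            for i in range(0, len(seq) - k + 1):
                self._index.setdefault(seq[i:i + k], []).append((name, i))

    def _seed_offsets(self, qlen: int) -> list[int]:
        if qlen <= self.k:
            return [0]
        offs = {0, (qlen - self.k) // 2, qlen - self.k}
        # extra seeds help when an error lands inside a seed
        offs.add((qlen - self.k) // 4)
        offs.add(3 * (qlen - self.k) // 4)
        return sorted(offs)

    def _hits_one_strand(self, seq: str, strand: str) -> list[Hit]:
        qlen = len(seq)
        if qlen < self.k:
            return []
        max_nm = int(self.max_mismatch_frac * qlen)
        cands: set[tuple[str, int]] = set()
        for off in self._seed_offsets(qlen):
            for contig, pos in self._index.get(seq[off:off + self.k], ()):
                start = pos - off
                if 0 <= start <= len(self.genome[contig]) - qlen:
                    cands.add((contig, start))
        hits = []
        for contig, start in cands:
            ref = self.genome[contig][start:start + qlen]
            nm = sum(a != b for a, b in zip(seq, ref))
            if nm <= max_nm:
                hits.append(Hit(contig, start, strand, nm))
        return hits

    def map_sequence(self, seq: str) -> list[Hit]:
        seq = seq.upper()
        hits = (self._hits_one_strand(seq, "+")
                + self._hits_one_strand(reverse_complement(seq), "-"))
        hits.sort(key=lambda h: (h.nm, h.contig, h.pos, h.strand))
        return hits

    def count_loci(self, seq: str, min_separation: int | None = None) -> int:
        """Distinct mapping loci (nearby/overlapping hits count once)."""
        hits = self.map_sequence(seq)
        if min_separation is None:
            min_separation = max(1, len(seq) // 2)
        loci: list[tuple[str, int]] = []
        for h in sorted(hits, key=lambda h: (h.contig, h.pos)):
            if loci and loci[-1][0] == h.contig and h.pos - loci[-1][1] < min_separation:
                continue
            loci.append((h.contig, h.pos))
        return len(loci)

    # -- read mapping (produces SAM records) ------------------------------

    def _mapq(self, hits: list[Hit]) -> int:
        if not hits:
            return 0
        if len(hits) == 1:
            return 60
        return 0 if hits[0].nm == hits[1].nm else 20

    def _to_record(self, name: str, seq: str, qual, hit: Hit | None,
                   mapq: int, header: pysam.AlignmentHeader,
                   flag_extra: int = 0) -> pysam.AlignedSegment:
        rec = pysam.AlignedSegment(header=header)
        rec.query_name = name
        rec.flag = flag_extra
        if hit is None:
            rec.is_unmapped = True
            rec.query_sequence = seq
            if qual is not None:
                rec.query_qualities = qual
            return rec
        if hit.strand == "-":
            rec.is_reverse = True
            rec.query_sequence = reverse_complement(seq)
            rec.query_qualities = qual[::-1] if qual is not None else None
        else:
            rec.query_sequence = seq
            rec.query_qualities = qual
        rec.reference_name = hit.contig
        rec.reference_start = hit.pos
        rec.mapping_quality = mapq
        rec.cigartuples = [(0, len(seq))]
        rec.set_tag("NM", hit.nm, "i")
        rec.set_tag("AS", len(seq) - 5 * hit.nm, "i")
        return rec

    def map_read(self, name: str, seq: str, qual=None,
                 header: pysam.AlignmentHeader | None = None) -> pysam.AlignedSegment:
        hits = self.map_sequence(seq)
        best = hits[0] if hits else None
        return self._to_record(name, seq, qual, best, self._mapq(hits), header)

    def map_pair(self, name: str, seq1: str, seq2: str, qual1=None, qual2=None,
                 header: pysam.AlignmentHeader | None = None,
                 frag_range: tuple[int, int] = (50, 2000)):
        """Map a pair jointly, preferring concordant (FR, in-range) placements."""
        h1, h2 = self.map_sequence(seq1), self.map_sequence(seq2)
        best_pair = None
        best_score = None
        for a in h1[:20]:
            for b in h2[:20]:
                if a.contig != b.contig or a.strand == b.strand:
                    continue
                lo = min(a.pos, b.pos)
                hi = max(a.pos + len(seq1), b.pos + len(seq2))
                if not frag_range[0] <= hi - lo <= frag_range[1]:
                    continue
                fwd, rev = (a, b) if a.strand == "+" else (b, a)
                if fwd.pos > rev.pos:
                    continue
                score = a.nm + b.nm
                if best_score is None or score < best_score:
                    best_pair, best_score, n_best = (a, b), score, 1
                elif score == best_score:
                    n_best += 1
        FLAG1 = 0x1 | 0x40
        FLAG2 = 0x1 | 0x80
        if best_pair is not None:
            a, b = best_pair
            mapq = 60 if n_best == 1 else 0
            r1 = self._to_record(name, seq1, qual1, a, mapq, header, FLAG1)
            r2 = self._to_record(name, seq2, qual2, b, mapq, header, FLAG2)
            r1.is_proper_pair = r2.is_proper_pair = True
        else:
            b1 = h1[0] if h1 else None
            b2 = h2[0] if h2 else None
            r1 = self._to_record(name, seq1, qual1, b1, self._mapq(h1), header, FLAG1)
            r2 = self._to_record(name, seq2, qual2, b2, self._mapq(h2), header, FLAG2)
        from .engine import update_mate_and_tlen
        update_mate_and_tlen(r1, r2)
        return r1, r2


class ExternalMapper:
    """Run an external aligner via a command template.

    The template receives ``{fastq1}``/``{fastq2}`` (or just ``{fastq1}``
    for single-end input) and must write SAM to standard output, e.g.::

        bwa mem {ref} {fastq1} {fastq2}
    """

    def __init__(self, command_template: str, paired: bool = True):
        self.command_template = command_template
        self.paired = paired

    def run(self, fastq1: str, fastq2: str | None, out_sam: str) -> None:
        cmd = self.command_template.format(fastq1=fastq1, fastq2=fastq2 or "")
        with open(out_sam, "w") as out:
            proc = subprocess.run(shlex.split(cmd), stdout=out,
                                  stderr=subprocess.PIPE, text=True)
        if proc.returncode != 0:
            raise RuntimeError(
                f"external mapper failed ({proc.returncode}):\n{proc.stderr}")
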