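"""Ground-truthed synthetic inputs: genome pairs, chains, reads, oracles.

A target-like "base" genome is edited into a source genome while the exact
base-level correspondence between the two is tracked.  Supported edits
cover the assembly-difference classes that matter for lift-over: SNVs,
short indels, inversions, segmental duplications present only in the
source (the target then looks "falsely collapsed"), segments duplicated
only in the target ("false duplication"), and novel source-only sequence
(a centromere stand-in).  The correspondence map doubles as the brute
brute-force lift oracle and can be serialized losslessly to a chain file.

Read simulation is substitution-only by default so every read's true
origin is unambiguous; the truth table records contig, 0-based leftmost
position and strand per end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from bisect import bisect_right
from typing import Iterable, Sequence

import numpy as np

from .engine import reverse_complement

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_genome(length: int, seed: int = 0, contig: str = "chr1") -> dict[str, str]:
    rng = np.random.default_rng(seed)
    return {contig: rng.choice(BASES, size=length).tobytes().decode()}


# ---------------------------------------------------------------------------
# Edit script
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Snv:
    pos: int  # base-genome coordinate


@dataclass(frozen=True)
class Insertion:  # source-only sequence
    pos: int
    seq: str


@dataclass(frozen=True)
class Deletion:  # present in target, absent from source
    pos: int
    length: int


@dataclass(frozen=True)
class Inversion:
    pos: int
    length: int


@dataclass(frozen=True)
class SourceDuplication:  # extra copy in source => false collapse in target
    pos: int
    length: int
    divergence: float = 0.02


@dataclass(frozen=True)
class TargetDuplication:  # extra copy in target => false duplication in target
    pos: int
    length: int


@dataclass(frozen=True)
class NovelSegment:  # novel source-only sequence (centromere stand-in)
    pos: int
    seq: str


STRUCTURAL = (Insertion, Deletion, Inversion, SourceDuplication,
              TargetDuplication, NovelSegment)


@dataclass(frozen=True)
class Block:
    """One colinear aligned block of the source<->target correspondence."""

    source_start: int
    source_end: int
    target_start: int
    target_end: int
    strand: str  # '+' or '-'

    def lift(self, p: int) -> int:
        if not self.source_start <= p < self.source_end:
            raise ValueError(p)
        if self.strand == "+":
            return self.target_start + (p - self.source_start)
        return self.target_end - 1 - (p - self.source_start)


@dataclass
class CorrespondenceMap:
    """Exact base-level pairing between one source and one target contig."""

    source_contig: str
    target_contig: str
    source_length: int
    target_length: int
    blocks: list[Block] = field(default_factory=list)

    def lift(self, pos: int) -> tuple[str, int, str] | None:
        """Brute-force oracle: target locus of a source base, or None."""
        starts = [b.source_start for b in self.blocks]
        i = bisect_right(starts, pos) - 1
        if i >= 0 and self.blocks[i].source_start <= pos < self.blocks[i].source_end:
            b = self.blocks[i]
            return (self.target_contig, b.lift(pos), b.strand)
        return None

    def invert(self) -> "CorrespondenceMap":
        blocks = [Block(b.target_start, b.target_end, b.source_start,
                        b.source_end, b.strand) for b in self.blocks]
        blocks.sort(key=lambda b: b.source_start)
        return CorrespondenceMap(self.target_contig, self.source_contig,
                                 self.target_length, self.source_length, blocks)


def oracle_lift(cmap: CorrespondenceMap, contig: str, pos: int):
    """Linear/dictionary oracle used as the reference in equivalence tests."""
    if contig != cmap.source_contig:
        return None
    return cmap.lift(pos)


# ---------------------------------------------------------------------------
# Applying an edit script
# ---------------------------------------------------------------------------


def _mutate(seq: str, positions: Iterable[int], rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    for p in positions:
        cur = arr[p]
        choices = BASES[BASES != cur]
        arr[p] = rng.choice(choices)
    return arr.tobytes().decode()


@dataclass
class GenomePair:
    source: dict[str, str]
    target: dict[str, str]
    cmap: CorrespondenceMap
    edits: list


def apply_edits(base: str, edits: Sequence, seed: int = 0,
                source_contig: str = "src", target_contig: str = "tgt") -> GenomePair:
    """Replay an edit script on a base (target-like) genome.

    Structural edits must be non-overlapping on the base; SNVs may not fall
    inside structural spans.  Deterministic given the script and seed (the
    seed only feeds duplication-divergence mutations).
    """
    rng = np.random.default_rng(seed)
    snvs = sorted(e.pos for e in edits if isinstance(e, Snv))
    struct = sorted((e for e in edits if isinstance(e, STRUCTURAL)),
                    key=lambda e: e.pos)
    spans = []
    for e in struct:
        ln = len(e.seq) if isinstance(e, (Insertion, NovelSegment)) else getattr(e, "length", 0)
        end = e.pos + (ln if not isinstance(e, (Insertion, NovelSegment)) else 0)
        spans.append((e.pos, max(end, e.pos)))
    for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
        if a2 < b1:
            raise ValueError("structural edits overlap on the base genome")
    for p in snvs:
        for a, b in spans:
            if a <= p < b:
                raise ValueError(f"SNV at {p} inside a structural edit span")

    src_parts: list[str] = []
    tgt_parts: list[str] = []
    blocks: list[Block] = []
    spos = tpos = 0
    snv_arr = np.array(snvs, dtype=np.int64)

    def emit_aligned(a: int, b: int) -> None:
        nonlocal spos, tpos
        if b <= a:
            return
        seg = base[a:b]
        lo, hi = np.searchsorted(snv_arr, [a, b])
        local = [int(p) - a for p in snv_arr[lo:hi]]
        src_seg = _mutate(seg, local, rng) if local else seg
        src_parts.append(src_seg)
        tgt_parts.append(seg)
        if (blocks and blocks[-1].strand == "+"
                and blocks[-1].source_end == spos
                and blocks[-1].target_end == tpos):
            prev = blocks.pop()
            blocks.append(Block(prev.source_start, spos + (b - a),
                                prev.target_start, tpos + (b - a), "+"))
        else:
            blocks.append(Block(spos, spos + (b - a), tpos, tpos + (b - a), "+"))
        spos += b - a
        tpos += b - a

    cursor = 0
    for e in struct:
        emit_aligned(cursor, e.pos)
        cursor = e.pos
        if isinstance(e, (Insertion, NovelSegment)):
            src_parts.append(e.seq)
            spos += len(e.seq)
        elif isinstance(e, Deletion):
            tgt_parts.append(base[e.pos:e.pos + e.length])
            tpos += e.length
            cursor = e.pos + e.length
        elif isinstance(e, Inversion):
            seg = base[e.pos:e.pos + e.length]
            src_parts.append(reverse_complement(seg))
            tgt_parts.append(seg)
            blocks.append(Block(spos, spos + e.length, tpos, tpos + e.length, "-"))
            spos += e.length
            tpos += e.length
            cursor = e.pos + e.length
        elif isinstance(e, SourceDuplication):
            emit_aligned(e.pos, e.pos + e.length)
            cursor = e.pos + e.length
            copy = base[e.pos:e.pos + e.length]
            if e.divergence > 0:
                n_mut = rng.binomial(e.length, e.divergence)
                pos_mut = rng.choice(e.length, size=n_mut, replace=False)
                copy = _mutate(copy, sorted(int(p) for p in pos_mut), rng)
            src_parts.append(copy)
            spos += e.length
        elif isinstance(e, TargetDuplication):
            emit_aligned(e.pos, e.pos + e.length)
            cursor = e.pos + e.length
            tgt_parts.append(base[e.pos:e.pos + e.length])
            tpos += e.length
        else:  # pragma: no cover
            raise TypeError(e)
    emit_aligned(cursor, len(base))

    source = "".join(src_parts)
    target = "".join(tgt_parts)
    cmap = CorrespondenceMap(source_contig, target_contig,
                             len(source), len(target), blocks)
    return GenomePair({source_contig: source}, {target_contig: target},
                      cmap, list(edits))


# ---------------------------------------------------------------------------
# Sampling an edit script
# ---------------------------------------------------------------------------

DEFAULT_EDIT_RATES = {
    "snv": 1e-3,          # per bp
    "ins": 1e-4,          # short source insertions, 1-20 bp
    "del": 1e-4,          # short source deletions, 1-20 bp
    "inv": 2e-5,          # inversions, 300-1500 bp
    "source_dup": 1e-5,   # source-only segmental duplications, 1000-4000 bp
    "target_dup": 1e-5,   # target-only duplications, 1000-4000 bp
    "novel": 1e-5,        # novel source-only segments, 5500-9000 bp
}

_SPAN_SIZES = {
    "inv": (300, 1500),
    "source_dup": (1000, 4000),
    "target_dup": (1000, 4000),
    "novel": (5500, 9000),
}


def sample_edits(base_length: int, edit_rates: dict | None = None,
                 seed: int = 0, dup_divergence: float = 0.02) -> list:
    """Draw a non-overlapping edit script at the given per-bp rates."""
    rates = dict(DEFAULT_EDIT_RATES)
    if edit_rates:
        rates.update(edit_rates)
    rng = np.random.default_rng(seed)
    margin = 50
    reserved: list[tuple[int, int]] = []

    def try_place(span: int) -> int | None:
        for _ in range(200):
            pos = int(rng.integers(margin, max(margin + 1, base_length - span - margin)))
            if all(pos + span + margin <= a or pos >= b + margin
                   for a, b in reserved):
                reserved.append((pos, pos + span))
                return pos
        return None

    edits: list = []
    total_struct = 0
    for kind in ("novel", "source_dup", "target_dup", "inv"):
        n = rng.poisson(rates[kind] * base_length)
        lo, hi = _SPAN_SIZES[kind]
        for _ in range(n):
            span = int(rng.integers(lo, hi + 1))
            if span + 2 * margin >= base_length:
                continue
            pos = try_place(span if kind != "novel" else 0)
            if pos is None:
                continue
            total_struct += 1
            if kind == "inv":
                edits.append(Inversion(pos, span))
            elif kind == "source_dup":
                edits.append(SourceDuplication(pos, span, dup_divergence))
            elif kind == "target_dup":
                edits.append(TargetDuplication(pos, span))
            else:
                seq = rng.choice(BASES, size=span).tobytes().decode()
                edits.append(NovelSegment(pos, seq))
    for kind in ("ins", "del"):
        n = rng.poisson(rates[kind] * base_length)
        for _ in range(n):
            ln = int(min(20, 1 + rng.geometric(0.35)))
            pos = try_place(ln if kind == "del" else 0)
            if pos is None:
                continue
            if kind == "ins":
                seq = rng.choice(BASES, size=ln).tobytes().decode()
                edits.append(Insertion(pos, seq))
            else:
                edits.append(Deletion(pos, ln))
    n_snv = rng.poisson(rates["snv"] * base_length)
    placed = 0
    attempts = 0
    while placed < n_snv and attempts < n_snv * 20:
        attempts += 1
        pos = int(rng.integers(0, base_length))
        if all(pos < a or pos >= b for a, b in reserved):
            edits.append(Snv(pos))
            placed += 1
    # deduplicate SNV positions
    seen = set()
    uniq = []
    for e in edits:
        if isinstance(e, Snv):
            if e.pos in seen:
                continue
            seen.add(e.pos)
        uniq.append(e)
    if len(uniq) > base_length:
        raise ValueError("edit script denser than the genome")
    return uniq


def dense_indel_script(base_length: int, n_gaps: int, seed: int = 0,
                       max_indel: int = 8) -> list:
    """Evenly spaced short indels producing ~n_gaps+1 aligned blocks.

    Unlike :func:`sample_edits` this places edits in one O(n) sweep, so
    scripts with thousands of gaps (dense chain stress tests) stay cheap.
    """
    if n_gaps >= base_length // 4:
        raise ValueError("edit script denser than the genome")
    rng = np.random.default_rng(seed)
    spacing = base_length // (n_gaps + 1)
    edits: list = []
    pos = spacing
    for i in range(n_gaps):
        ln = int(rng.integers(1, max_indel + 1))
        if rng.integers(0, 2) == 0:
            seq = rng.choice(BASES, size=ln).tobytes().decode()
            edits.append(Insertion(pos, seq))
            pos += spacing
        else:
            edits.append(Deletion(pos, ln))
            pos += spacing + ln
        if pos >= base_length - max_indel - 1:
            break
    return edits


def generate_genome_pair(base_length: int = 100_000,
                         edit_rates: dict | None = None,
                         seed: int = 0,
                         source_contig: str = "src",
                         target_contig: str = "tgt") -> GenomePair:
    """Sample a base genome and an edit script, then replay the script."""
    base = random_genome(base_length, seed=seed)["chr1"]
    edits = sample_edits(base_length, edit_rates, seed=seed + 1)
    return apply_edits(base, edits, seed=seed + 2,
                       source_contig=source_contig, target_contig=target_contig)


# ---------------------------------------------------------------------------
# Chain emission
# ---------------------------------------------------------------------------


def emit_chain(cmap: CorrespondenceMap) -> str:
    """Serialize a correspondence map as chain-format text.

    Runs of co-linear '+' blocks become one chain (gap lines carry
    dsource/dtarget); every '-' block becomes its own single-line chain
    with reverse-strand target coordinates.
    """
    lines: list[str] = []
    chain_id = 1

    def flush_plus(run: list[Block]) -> None:
        nonlocal chain_id
        if not run:
            return
        score = sum(b.source_end - b.source_start for b in run)
        head = (f"chain {score} {cmap.source_contig} {cmap.source_length} + "
                f"{run[0].source_start} {run[-1].source_end} "
                f"{cmap.target_contig} {cmap.target_length} + "
                f"{run[0].target_start} {run[-1].target_end} {chain_id}")
        lines.append(head)
        for a, b in zip(run, run[1:]):
            size = a.source_end - a.source_start
            ds = b.source_start - a.source_end
            dt = b.target_start - a.target_end
            lines.append(f"{size} {ds} {dt}")
        last = run[-1]
        lines.append(f"{last.source_end - last.source_start}")
        lines.append("")
        chain_id += 1

    run: list[Block] = []
    for blk in cmap.blocks:
        if blk.strand == "+":
            run.append(blk)
            continue
        flush_plus(run)
        run = []
        size = blk.source_end - blk.source_start
        t_rs = cmap.target_length - blk.target_end
        t_re = cmap.target_length - blk.target_start
        lines.append(
            f"chain {size} {cmap.source_contig} {cmap.source_length} + "
            f"{blk.source_start} {blk.source_end} "
            f"{cmap.target_contig} {cmap.target_length} - {t_rs} {t_re} {chain_id}")
        lines.append(f"{size}")
        lines.append("")
        chain_id += 1
    flush_plus(run)
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruthEntry:
    contig: str
    pos: int      # 0-based leftmost base of the read on its genome of origin
    strand: str
    haplotype: int = 0


@dataclass
class SimulatedPair:
    name: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str
    truth1: TruthEntry
    truth2: TruthEntry


TruthTable = dict[tuple[str, int], TruthEntry]


def simulate_reads(genomes: dict[str, str] | Sequence[dict[str, str]],
                   n_pairs: int, read_len: int = 100,
                   frag_mean: float = 350.0, frag_sd: float = 35.0,
                   err_rate: float = 0.002, seed: int = 0,
                   name_prefix: str = "rd") -> tuple[list[SimulatedPair], TruthTable]:
    """Simulate paired-end reads with known origins.

    ``genomes`` is one contig dict (haploid) or a sequence of contig dicts
    (haplotypes, sampled uniformly).  Fragments start uniformly along each
    contig (contigs weighted by length); R1/R2 orientations are swapped
    with probability 1/2; substitution errors occur at ``err_rate``.
    Contigs shorter than the fragment length are skipped.
    """
    if isinstance(genomes, dict):
        haplotypes = [genomes]
    else:
        haplotypes = list(genomes)
    if frag_mean < read_len:
        raise ValueError("fragment length must be >= read length")
    rng = np.random.default_rng(seed)
    pairs: list[SimulatedPair] = []
    truth: TruthTable = {}
    qual = "I" * read_len

    def add_errors(seq: str) -> str:
        n_err = rng.binomial(len(seq), err_rate)
        if n_err == 0:
            return seq
        pos = rng.choice(len(seq), size=n_err, replace=False)
        return _mutate(seq, sorted(int(p) for p in pos), rng)

    for i in range(n_pairs):
        hap_i = int(rng.integers(0, len(haplotypes))) if len(haplotypes) > 1 else 0
        hap = haplotypes[hap_i]
        contigs = [c for c in sorted(hap) if len(hap[c]) >= frag_mean + 4 * frag_sd]
        if not contigs:
            raise ValueError("no contig long enough for the fragment length")
        weights = np.array([len(hap[c]) for c in contigs], dtype=float)
        contig = contigs[int(rng.choice(len(contigs), p=weights / weights.sum()))]
        seq = hap[contig]
        frag = int(max(read_len, round(rng.normal(frag_mean, frag_sd))))
        frag = min(frag, len(seq))
        start = int(rng.integers(0, len(seq) - frag + 1))
        fwd = seq[start:start + read_len]
        rev = reverse_complement(seq[start + frag - read_len:start + frag])
        name = f"{name_prefix}{i:07d}"
        if rng.integers(0, 2) == 0:
            s1, s2 = fwd, rev
            t1 = TruthEntry(contig, start, "+", hap_i)
            t2 = TruthEntry(contig, start + frag - read_len, "-", hap_i)
        else:
            s1, s2 = rev, fwd
            t1 = TruthEntry(contig, start + frag - read_len, "-", hap_i)
            t2 = TruthEntry(contig, start, "+", hap_i)
        s1, s2 = add_errors(s1), add_errors(s2)
        pairs.append(SimulatedPair(name, s1, s2, qual, qual, t1, t2))
        truth[(name, 1)] = t1
        truth[(name, 2)] = t2
    return pairs, truth


def write_fastq(pairs: Sequence[SimulatedPair], path1: str, path2: str) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.name}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.name}/2\n{p.seq2}\n+\n{p.qual2}\n")


def write_truth(truth: TruthTable, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("name\tend\tcontig\tpos\tstrand\thaplotype\n")
        for (name, end), t in sorted(truth.items()):
            fh.write(f"{name}\t{end}\t{t.contig}\t{t.pos}\t{t.strand}\t{t.haplotype}\n")


def load_truth(path: str) -> TruthTable:
    truth: TruthTable = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            name, end, contig, pos, strand, hap = line.rstrip("\n").split("\t")
            truth[(name, int(end))] = TruthEntry(contig, int(pos), strand, int(hap))
    return truth


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def evaluate_correctness(mappings, truth: TruthTable, tol: int = 10) -> dict:
    """Fraction of reads whose leftmost mapped position is within ``tol`` bp
    of the simulated origin on the same contig.

    ``mappings`` is an iterable of primary pysam records or of
    ``(name, end, contig, pos)`` tuples (contig ``None`` = unmapped).
    Reads missing from ``mappings`` (or unmapped) count as incorrect; a
    mapping absent from the truth table is an error.
    """
    seen: dict[tuple[str, int], tuple[str | None, int | None]] = {}
    for m in mappings:
        if isinstance(m, tuple):
            name, end, contig, pos = m
        else:
            if m.is_secondary or m.is_supplementary:
                continue
            name = m.query_name
            end = 2 if (m.is_paired and m.is_read2) else 1
            contig = None if m.is_unmapped else m.reference_name
            pos = None if m.is_unmapped else m.reference_start
        if (name, end) not in truth:
            raise KeyError(f"read {name}/{end} absent from the truth table")
        seen[(name, end)] = (contig, pos)
    n_total = len(truth)
    n_correct = 0
    for key, t in truth.items():
        contig, pos = seen.get(key, (None, None))
        if contig == t.contig and pos is not None and abs(pos - t.pos) <= tol:
            n_correct += 1
    return {
        "n_correct": n_correct,
        "n_total": n_total,
        "fraction": n_correct / n_total if n_total else float("nan"),
    }


def aggregate_f1(tp: float, fp: float, fn: float) -> float:
    """F1 = TP / (TP + 0.5*(FP + FN)); summing counts first aggregates datasets."""
    if tp < 0 or fp < 0 or fn < 0:
        raise ValueError("counts must be non-negative")
    denom = tp + 0.5 * (fp + fn)
    if denom == 0:
        return float("nan")
    return tp / denom


def write_fasta(genome: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    genome: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    genome[name] = "".join(parts)
                name = line[1:].split()[0]
                parts = []
            elif line:
                parts.append(line)
    if name is not None:
        genome[name] = "".join(parts)
    return genome
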