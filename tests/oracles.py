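"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately simple and slow: linear scans, explicit
per-base maps, full dynamic programs written from the recurrence with no
shared code with the package internals.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def linear_scan_lift(intervals, contig: str, p: int):
    """Reference lift: scan every interval; None if uncovered.

    ``intervals`` is any iterable of objects with source_contig,
    source_start/end, target_contig/start/end and strand.
    """
    for iv in intervals:
        if iv.source_contig != contig:
            continue
        if iv.source_start <= p < iv.source_end:
            if iv.strand == "+":
                return (iv.target_contig, iv.target_start + (p - iv.source_start), "+")
            return (iv.target_contig, iv.target_end - 1 - (p - iv.source_start), "-")
    return None


def brute_rank(positions, p: int) -> int:
    """Number of set positions strictly below p."""
    return sum(1 for q in positions if q < p)


def aligned_pairs_from_runs(runs, pos):
    """(query_index, ref_pos) pairs implied by a CIGAR, from first principles."""
    qi, ri = 0, pos
    pairs = []
    for op, ln in runs:
        if op in ("M", "=", "X"):
            for _ in range(ln):
                pairs.append((qi, ri))
                qi += 1
                ri += 1
        elif op in ("I", "S"):
            qi += ln
        elif op in ("D", "N"):
            ri += ln
        elif op in ("H", "P"):
            pass
        else:
            raise ValueError(op)
    return pairs


def expected_target_pairing(source_runs, source_pos, cmap, query_len,
                            flipped: bool):
    """Oracle base pairing of a lifted read: source pairing composed with
    the correspondence map.  Returns {lifted_query_index: target_pos};
    source bases with no target image are absent."""
    pairing = {}
    for qi, sp in aligned_pairs_from_runs(source_runs, source_pos):
        hit = cmap.lift(sp)
        if hit is None:
            continue
        _, tp, strand = hit
        out_qi = (query_len - 1 - qi) if flipped else qi
        pairing[out_qi] = tp
    return pairing


def affine_dp_score(query: str, ref: str, match: int, mismatch: int,
                    gap_open: int, gap_extend: int) -> int:
    """Score-only affine-gap fit alignment (query global, ref free ends).

    Full three-matrix recurrence over numpy arrays; gap of length L costs
    gap_open + L*gap_extend.
    """
    n, m = len(query), len(ref)
    NEG = -10 ** 9
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    I = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    D = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    for i in range(1, n + 1):
        H[i, 0] = NEG
    for i in range(1, n + 1):
        for j in range(0, m + 1):
            I[i, j] = max(H[i - 1, j] - gap_open - gap_extend,
                          I[i - 1, j] - gap_extend)
            if j > 0:
                D[i, j] = max(H[i, j - 1] - gap_open - gap_extend,
                              D[i, j - 1] - gap_extend)
                sub = match if query[i - 1] == ref[j - 1] else -mismatch
                H[i, j] = max(H[i - 1, j - 1] + sub, I[i, j], D[i, j])
            else:
                H[i, j] = I[i, j]
    return int(H[n].max())


def brute_mappability(genome: dict[str, str], k: int, e: int):
    """All-pairs Hamming comparison, one window at a time."""
    seqs = {n: np.frombuffer(s.upper().encode(), dtype=np.uint8)
            for n, s in sorted(genome.items())}
    windows = []
    for name, arr in seqs.items():
        for i in range(len(arr) - k + 1):
            windows.append((name, i, arr[i:i + k]))
    out = {name: np.zeros(max(0, len(arr) - k + 1)) for name, arr in seqs.items()}
    mat = np.stack([w[2] for w in windows]) if windows else None
    for idx, (name, i, w) in enumerate(windows):
        dists = (mat != w).sum(axis=1)
        count = int((dists <= e).sum())
        out[name][i] = 1.0 / count
    return out
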