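"""Localized affine-gap realignment of lifted reads.

Lifting across chain gaps preserves base pairing but may leave a
non-optimal arrangement of gaps and mismatches (e.g. an insertion next to
a deletion that cancel out).  This module refines a lifted alignment by
running an affine-gap dynamic program of the read's aligned core against a
padded window of the target reference: global in the query, free at both
reference ends ("fit" alignment).  Scoring presets mirror the conventions
of popular aligners (gap of length L costs open + L*extend).
"""

from __future__ import annotations

from dataclasses import dataclass

NEG_INF = float("-inf")


@dataclass(frozen=True)
class ScoringPreset:
    name: str
    match: int
    mismatch: int      # penalty, positive
    gap_open: int      # penalty, positive
    gap_extend: int    # penalty, positive

    def substitution(self, a: str, b: str) -> int:
        return self.match if a == b else -self.mismatch


#: Default presets modeled on common aligner scoring schemes.
DEFAULT_PRESETS = {
    "bwa-mem": ScoringPreset("bwa-mem", match=1, mismatch=4, gap_open=6, gap_extend=1),
    "bowtie2": ScoringPreset("bowtie2", match=0, mismatch=6, gap_open=5, gap_extend=3),
    "minimap2": ScoringPreset("minimap2", match=2, mismatch=4, gap_open=4, gap_extend=2),
}


def score_alignment(runs, query: str, ref: str, preset: ScoringPreset) -> int:
    """Score an existing alignment (CIGAR vs ref slice) under a preset.

    ``query`` is the aligned core (soft/hard clips excluded); ``ref`` starts
    at the alignment's reference start.  Clip runs are ignored.
    """
    qi = ri = 0
    score = 0
    for op, ln in runs:
        if op in ("S", "H", "P"):
            continue
        if op in ("M", "=", "X"):
            for k in range(ln):
                score += preset.substitution(query[qi + k], ref[ri + k])
            qi += ln
            ri += ln
        elif op == "I":
            score -= preset.gap_open + preset.gap_extend * ln
            qi += ln
        elif op in ("D", "N"):
            score -= preset.gap_open + preset.gap_extend * ln
            ri += ln
        else:
            raise ValueError(f"unsupported op {op}")
    return score


def affine_fit_align(query: str, ref: str, preset: ScoringPreset):
    """Optimal affine-gap alignment: query global, reference free at ends.

    Returns ``(score, runs, ref_start)`` where ``runs`` is the CIGAR of the
    aligned core and ``ref_start`` the 0-based offset of its first aligned
    base within ``ref``.
    """
    n, m = len(query), len(ref)
    if n == 0:
        raise ValueError("empty query")
    if m == 0:
        raise ValueError("empty reference window")
    go, ge = preset.gap_open, preset.gap_extend

    # DP rows over ref positions 0..m; traceback: 0=diag, 1=ins(query), 2=del(ref)
    H_prev = [0.0] * (m + 1)          # free leading reference skip
    I_prev = [NEG_INF] * (m + 1)
    tb_h = [bytearray(m + 1) for _ in range(n + 1)]
    tb_i = [bytearray(m + 1) for _ in range(n + 1)]  # 1 => extend
    tb_d = [bytearray(m + 1) for _ in range(n + 1)]

    for i in range(1, n + 1):
        qc = query[i - 1]
        H_cur = [NEG_INF] * (m + 1)
        I_cur = [NEG_INF] * (m + 1)
        D_cur = NEG_INF
        # j = 0: query prefix unaligned => insertion run
        open_i = H_prev[0] - go - ge
        ext_i = I_prev[0] - ge
        I_cur[0] = open_i if open_i >= ext_i else ext_i
        tb_i[i][0] = 0 if open_i >= ext_i else 1
        H_cur[0] = I_cur[0]
        tb_h[i][0] = 1
        row_tb_h, row_tb_i, row_tb_d = tb_h[i], tb_i[i], tb_d[i]
        for j in range(1, m + 1):
            open_i = H_prev[j] - go - ge
            ext_i = I_prev[j] - ge
            if open_i >= ext_i:
                I_cur[j] = open_i
                row_tb_i[j] = 0
            else:
                I_cur[j] = ext_i
                row_tb_i[j] = 1
            open_d = H_cur[j - 1] - go - ge
            ext_d = D_cur - ge
            if open_d >= ext_d:
                D_cur = open_d
                row_tb_d[j] = 0
            else:
                D_cur = ext_d
                row_tb_d[j] = 1
            diag = H_prev[j - 1] + (preset.match if qc == ref[j - 1] else -preset.mismatch)
            best, who = diag, 0
            if I_cur[j] > best:
                best, who = I_cur[j], 1
            if D_cur > best:
                best, who = D_cur, 2
            H_cur[j] = best
            row_tb_h[j] = who
        H_prev, I_prev = H_cur, I_cur

    j_best = max(range(m + 1), key=lambda j: H_prev[j])
    score = H_prev[j_best]

    # traceback
    runs_rev: list[tuple[str, int]] = []

    def push(op: str):
        if runs_rev and runs_rev[-1][0] == op:
            runs_rev[-1] = (op, runs_rev[-1][1] + 1)
        else:
            runs_rev.append((op, 1))

    i, j = n, j_best
    state = 0  # in H
    while i > 0:
        if state == 0:
            who = tb_h[i][j]
            if who == 0:
                push("M")
                i -= 1
                j -= 1
            elif who == 1:
                state = 1
            else:
                state = 2
        elif state == 1:
            push("I")
            ext = tb_i[i][j]
            i -= 1
            state = 1 if ext else 0
        else:
            push("D")
            ext = tb_d[i][j]
            j -= 1
            state = 2 if ext else 0
    ref_start = j
    runs = [(op, ln) for op, ln in reversed(runs_rev)]
    return int(score), runs, ref_start
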