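"""CIGAR run utilities and single-pass rewriting across chain gaps.

The central routine, :func:`update_cigar_runs`, converts a CIGAR expressed
against the source reference into one valid on the target, given the
ordered chain gaps overlapping the alignment.  It makes one pass over the
CIGAR runs and one over the gap list (O(r+g) operations):

* read bases paired with ``dsource`` (source-only) bases become ``I`` runs,
  merged into flanking soft clips at the alignment ends;
* interior ``dtarget`` (target-only) stretches become ``D`` runs;
* original ``D``/``N`` runs overlapping a ``dsource`` gap shrink by the
  overlap;
* ``I``/``S``/``H`` runs consume no source reference and pass through
  untouched;
* leading/trailing deletions are removed, adjacent same-op runs merged, and
  the query-consuming length is preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

# pysam cigar op codes <-> characters
OPS = "MIDNSHP=X"
CODE = {c: i for i, c in enumerate(OPS)}
QUERY_OPS = set("MIS=X")
REF_OPS = set("MDN=X")
MATCH_OPS = set("M=X")
CLIP_OPS = set("SH")


class UnliftableCigar(ValueError):
    """The alignment cannot be expressed against the target reference."""


def runs_from_cigartuples(cigartuples) -> list[tuple[str, int]]:
    return [(OPS[op], ln) for op, ln in cigartuples]


def runs_to_cigartuples(runs: Iterable[tuple[str, int]]) -> list[tuple[int, int]]:
    return [(CODE[op], ln) for op, ln in runs]


def runs_to_string(runs: Iterable[tuple[str, int]]) -> str:
    return "".join(f"{ln}{op}" for op, ln in runs) or "*"


def runs_from_string(cigar: str) -> list[tuple[str, int]]:
    runs: list[tuple[str, int]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        elif ch in OPS:
            if not num:
                raise ValueError(f"bad CIGAR {cigar!r}")
            runs.append((ch, int(num)))
            num = ""
        else:
            raise ValueError(f"bad CIGAR op {ch!r}")
    if num:
        raise ValueError(f"trailing number in CIGAR {cigar!r}")
    return runs


def query_length(runs: Iterable[tuple[str, int]], include_hard: bool = False) -> int:
    ops = QUERY_OPS | ({"H"} if include_hard else set())
    return sum(ln for op, ln in runs if op in ops)


def reference_span(runs: Iterable[tuple[str, int]]) -> int:
    return sum(ln for op, ln in runs if op in REF_OPS)


def merge_runs(runs: Iterable[tuple[str, int]]) -> list[tuple[str, int]]:
    out: list[list] = []
    for op, ln in runs:
        if ln <= 0:
            continue
        if out and out[-1][0] == op:
            out[-1][1] += ln
        else:
            out.append([op, ln])
    return [(op, ln) for op, ln in out]


@dataclass
class CigarUpdate:
    """Result of lifting a CIGAR across chain gaps (source orientation)."""

    runs: list[tuple[str, int]]
    first_match_src: int   # source position of the first aligned (M/=/X) base
    last_match_src: int    # source position of the last aligned base
    gaps_crossed: int
    new_head_clip: int     # query bases newly soft-clipped at alignment start
    new_tail_clip: int     # query bases newly soft-clipped at alignment end


def _normalize(raw: list[list], head_hard: int, tail_hard: int) -> list[tuple[str, int]]:
    """Strip edge deletions, fold edge insertions into soft clips, merge."""
    runs = [(op, ln) for op, ln in raw if ln > 0]
    first = last = None
    for i, (op, _) in enumerate(runs):
        if op in MATCH_OPS:
            if first is None:
                first = i
            last = i
    if first is None:
        raise UnliftableCigar("no aligned bases remain")
    head_soft = sum(ln for op, ln in runs[:first] if op in ("S", "I"))
    tail_soft = sum(ln for op, ln in runs[last + 1:] if op in ("S", "I"))
    mid = merge_runs(runs[first:last + 1])
    out: list[tuple[str, int]] = []
    if head_hard:
        out.append(("H", head_hard))
    if head_soft:
        out.append(("S", head_soft))
    out.extend(mid)
    if tail_soft:
        out.append(("S", tail_soft))
    if tail_hard:
        out.append(("H", tail_hard))
    return out


def update_cigar_runs(
    runs: Sequence[tuple[str, int]],
    pos: int,
    gaps,
    chain_end: int,
    allowed_overhang: int = 0,
) -> CigarUpdate:
    """Rewrite a source-coordinate CIGAR for the target reference.

    Parameters
    ----------
    runs:
        CIGAR runs as (op_char, length), source orientation.
    pos:
        0-based source position of the first reference-consuming base.
    gaps:
        Chain gaps (objects with ``source_break``, ``dsource``, ``dtarget``)
        ordered by ``source_break``; gaps wholly before ``pos`` are ignored.
    chain_end:
        Source end of the chain's final aligned interval; alignment bases
        beyond it have no target image.
    allowed_overhang:
        Maximum number of query bases past ``chain_end`` (or stranded before
        the first covered base) that may be soft-clipped before the
        alignment is declared unliftable.

    Raises
    ------
    UnliftableCigar
        If more than ``allowed_overhang`` query bases fall outside the
        chain, or no aligned bases remain.
    """
    gaps = [g for g in gaps if g.source_break + g.dsource > pos]
    out: list[list] = []
    head_hard = tail_hard = 0
    if runs and runs[0][0] == "H":
        head_hard = runs[0][1]
        runs = runs[1:]
    if runs and runs[-1][0] == "H":
        tail_hard = runs[-1][1]
        runs = runs[:-1]

    def emit(op: str, ln: int) -> None:
        if ln <= 0:
            return
        if out and out[-1][0] == op:
            out[-1][1] += ln
        else:
            out.append([op, ln])

    src = pos
    gi = 0
    gaps_crossed = 0
    beyond_chain_query = 0
    first_match = last_match = None
    orig_head_clip = runs[0][1] if runs and runs[0][0] == "S" else 0
    orig_tail_clip = runs[-1][1] if runs and runs[-1][0] == "S" else 0

    for op, ln in runs:
        if op in ("S", "I", "P"):
            emit(op, ln)
            continue
        consumes_query = op in MATCH_OPS
        rem = ln
        while rem > 0:
            if gi < len(gaps) and src >= gaps[gi].source_break:
                zone_end = gaps[gi].source_break + gaps[gi].dsource
                take = min(rem, zone_end - src)
                if consumes_query:
                    emit("I", take)
                src += take
                rem -= take
                if src == zone_end:
                    emit("D", gaps[gi].dtarget)
                    gaps_crossed += 1
                    gi += 1
                continue
            if src >= chain_end:
                if consumes_query:
                    emit("I", rem)
                    beyond_chain_query += rem
                src += rem
                rem = 0
                continue
            next_b = min(
                gaps[gi].source_break if gi < len(gaps) else chain_end,
                chain_end,
            )
            take = min(rem, next_b - src)
            if take > 0:
                emit(op, take)
                if consumes_query:
                    if first_match is None:
                        first_match = src
                    last_match = src + take - 1
                src += take
                rem -= take
            elif src == next_b == chain_end:
                # interior position coincides with chain end; loop handles it
                continue

    if beyond_chain_query > allowed_overhang:
        raise UnliftableCigar(
            f"{beyond_chain_query} query bases extend past the final chain "
            f"interval (allowed {allowed_overhang})")
    if first_match is None:
        raise UnliftableCigar("no aligned bases remain")

    norm = _normalize(out, head_hard, tail_hard)
    new_head = (norm[1][1] if head_hard and len(norm) > 1 and norm[1][0] == "S"
                else norm[0][1] if not head_hard and norm[0][0] == "S" else 0)
    new_tail = (norm[-2][1] if tail_hard and len(norm) > 1 and norm[-2][0] == "S"
                else norm[-1][1] if not tail_hard and norm[-1][0] == "S" else 0)
    if new_head - orig_head_clip > allowed_overhang:
        raise UnliftableCigar(
            f"{new_head - orig_head_clip} query bases precede the first "
            f"covered base (allowed {allowed_overhang})")
    return CigarUpdate(
        runs=norm,
        first_match_src=first_match,
        last_match_src=last_match,
        gaps_crossed=gaps_crossed,
        new_head_clip=max(0, new_head - orig_head_clip),
        new_tail_clip=max(0, new_tail - orig_tail_clip),
    )


def update_cigar(cigar, pos: int, gaps, chain_end: int | None = None):
    """Spec-shaped convenience wrapper: CIGAR in, lifted CIGAR out.

    ``cigar`` may be a string or a run list; the return type matches the
    input.  ``chain_end`` defaults to "no boundary" (only gap arithmetic).
    """
    as_string = isinstance(cigar, str)
    runs = runs_from_string(cigar) if as_string else list(cigar)
    if chain_end is None:
        chain_end = float("inf")
    upd = update_cigar_runs(runs, pos, gaps, chain_end,
                            allowed_overhang=float("inf"))
    return runs_to_string(upd.runs) if as_string else upd.runs
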