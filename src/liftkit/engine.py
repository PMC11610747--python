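"""Lift full SAM records between references.

Builds on :mod:`liftkit.chain` (where does a position go?) and
:mod:`liftkit.cigar` (how does the alignment change across chain gaps?) to
rewrite complete alignment records: position, contig, strand, CIGAR, mate
fields and template length, and optionally the NM/MD tags and a localized
DP refinement of the alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pysam

from .chain import ChainIndex, LiftedPoint, Unliftable
from .cigar import (
    MATCH_OPS,
    UnliftableCigar,
    merge_runs,
    query_length,
    reference_span,
    runs_from_cigartuples,
    runs_to_cigartuples,
    update_cigar_runs,
)
from .realign import ScoringPreset, affine_fit_align, score_alignment

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtnRYKMSWBVDH", "TGCANtgcanYRMKSWVBHD")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def make_target_header(idx: ChainIndex, sort_order: str = "unsorted",
                       program: str | None = "liftkit") -> pysam.AlignmentHeader:
    """SAM header whose contigs/lengths come from the index's target genome."""
    d = {
        "HD": {"VN": "1.6", "SO": sort_order},
        "SQ": [{"SN": name, "LN": length}
               for name, length in sorted(idx.target_lengths.items())],
    }
    if program:
        d["PG"] = [{"ID": program, "PN": program}]
    return pysam.AlignmentHeader.from_dict(d)


def make_source_header(idx: ChainIndex) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length}
               for name, length in sorted(idx.source_lengths.items())],
    })


@dataclass
class LiftResult:
    """Outcome of lifting one record.

    ``status`` is "lifted" or "unliftable".  ``source_record`` is always the
    input; ``record`` is the lifted record when status == "lifted".
    """

    status: str
    source_record: pysam.AlignedSegment
    record: pysam.AlignedSegment | None = None
    reason: str | None = None
    gaps_crossed: int = 0
    bases_clipped: int = 0
    strand_flipped: bool = False

    @property
    def lifted(self) -> bool:
        return self.status == "lifted"

    def __bool__(self) -> bool:
        return self.lifted


def _copy_record(rec: pysam.AlignedSegment,
                 header: pysam.AlignmentHeader) -> pysam.AlignedSegment:
    out = pysam.AlignedSegment(header=header)
    out.query_name = rec.query_name
    out.flag = rec.flag
    out.mapping_quality = rec.mapping_quality
    out.query_sequence = rec.query_sequence
    out.query_qualities = rec.query_qualities
    out.set_tags(rec.get_tags(with_value_type=True))
    return out


def lift_alignment(rec: pysam.AlignedSegment, idx: ChainIndex,
                   target_header: pysam.AlignmentHeader) -> LiftResult:
    """Lift one SAM record from source to target coordinates.

    The leftmost aligned base is located with a constant-time point query;
    the CIGAR is rewritten in a single pass over runs and overlapping chain
    gaps.  If the covering interval is on the '-' strand the sequence is
    reverse-complemented, qualities and CIGAR reversed, and the reverse
    flag toggled.  Unmapped records pass through, re-placed when their
    stored position lifts.
    """
    if rec.is_unmapped:
        out = _copy_record(rec, target_header)
        if rec.reference_id >= 0 and rec.reference_start >= 0:
            lp = idx.lift_position(rec.reference_name, rec.reference_start)
            if lp:
                out.reference_name = lp.target_contig
                out.reference_start = lp.target_pos
        return LiftResult("lifted", rec, out)

    contig = rec.reference_name
    p = rec.reference_start
    lp = idx.lift_position(contig, p)
    if isinstance(lp, Unliftable):
        return LiftResult("unliftable", rec, reason=lp.reason)
    chain = idx.chains[lp.chain_id]

    runs = runs_from_cigartuples(rec.cigartuples)
    try:
        upd = update_cigar_runs(runs, p, chain.gaps, chain.last_source_end,
                                allowed_overhang=idx.allowed_gap)
    except UnliftableCigar as exc:
        return LiftResult("unliftable", rec, reason=str(exc))

    flipped = chain.strand == "-"
    if flipped:
        new_pos = chain.lift(upd.last_match_src)
        new_runs = list(reversed(upd.runs))
    else:
        new_pos = chain.lift(upd.first_match_src)
        new_runs = upd.runs
    if new_pos is None:
        return LiftResult("unliftable", rec, reason="aligned base outside chain")
    tlen_contig = idx.target_lengths.get(chain.target_contig)
    if tlen_contig is None:
        return LiftResult("unliftable", rec, reason="target contig unknown")
    if new_pos + reference_span(new_runs) > tlen_contig:
        return LiftResult("unliftable", rec, reason="lifted past target contig end")

    out = _copy_record(rec, target_header)
    out.reference_name = chain.target_contig
    out.reference_start = new_pos
    if flipped:
        seq = rec.query_sequence
        quals = rec.query_qualities
        if seq is not None:
            out.query_sequence = reverse_complement(seq)
        if quals is not None:
            out.query_qualities = quals[::-1]
        out.is_reverse = not rec.is_reverse
    out.cigartuples = runs_to_cigartuples(new_runs)
    return LiftResult(
        "lifted", rec, out,
        gaps_crossed=upd.gaps_crossed,
        bases_clipped=upd.new_head_clip + upd.new_tail_clip,
        strand_flipped=flipped,
    )


def update_mate_and_tlen(r1: pysam.AlignedSegment, r2: pysam.AlignedSegment,
                         proper_frag_range: tuple[int, int] | None = None) -> None:
    """Make a lifted pair's mate fields and template length mutually consistent.

    TLEN is the signed outer distance (leftmost end positive).  The
    proper-pair flag requires both ends mapped to the same contig in
    opposite orientations and, when ``proper_frag_range`` is given, an
    outer distance within it.
    """
    for a, b in ((r1, r2), (r2, r1)):
        a.mate_is_unmapped = b.is_unmapped
        a.mate_is_reverse = b.is_reverse
        if b.is_unmapped:
            a.next_reference_id = a.reference_id if not a.is_unmapped else -1
            a.next_reference_start = a.reference_start if not a.is_unmapped else -1
        else:
            a.next_reference_name = b.reference_name
            a.next_reference_start = b.reference_start
    if (r1.is_unmapped or r2.is_unmapped
            or r1.reference_id != r2.reference_id):
        r1.template_length = r2.template_length = 0
        r1.is_proper_pair = r2.is_proper_pair = False
        return
    lo = min(r1.reference_start, r2.reference_start)
    hi = max(r1.reference_end, r2.reference_end)
    tlen = hi - lo
    if r1.reference_start <= r2.reference_start:
        r1.template_length, r2.template_length = tlen, -tlen
    else:
        r1.template_length, r2.template_length = -tlen, tlen
    proper = r1.is_reverse != r2.is_reverse
    if proper_frag_range is not None:
        proper = proper and proper_frag_range[0] <= tlen <= proper_frag_range[1]
    r1.is_proper_pair = r2.is_proper_pair = proper


def _fetch(reference, contig: str, start: int, end: int) -> str:
    """Fetch an upper-cased reference slice from a dict / FastaFile / Fasta."""
    if isinstance(reference, dict):
        return reference[contig][start:end].upper()
    if hasattr(reference, "fetch"):
        return reference.fetch(contig, start, end).upper()
    return str(reference[contig][start:end]).upper()


def recompute_nm_md(rec: pysam.AlignedSegment, reference) -> pysam.AlignedSegment:
    """Recompute the NM (edit distance) and MD tags against the reference.

    NM counts mismatches plus inserted plus deleted bases; MD encodes
    matched run lengths, mismatched reference bases, and deleted reference
    sequence per the SAM conventions.  Idempotent; records lacking a query
    sequence have the tags dropped with a warning.
    """
    if rec.is_unmapped:
        return rec
    seq = rec.query_sequence
    if seq is None:
        logger.warning("record %s has no sequence; dropping NM/MD", rec.query_name)
        for tag in ("NM", "MD"):
            if rec.has_tag(tag):
                rec.set_tag(tag, None)
        return rec
    ref = _fetch(reference, rec.reference_name, rec.reference_start,
                 rec.reference_start + rec.reference_length)
    seq = seq.upper()
    qi = ri = 0
    nm = 0
    md_parts: list[str] = []
    match_run = 0
    for op, ln in runs_from_cigartuples(rec.cigartuples):
        if op in ("S", "H", "P"):
            if op == "S":
                qi += ln
            continue
        if op in MATCH_OPS:
            for k in range(ln):
                if seq[qi + k] == ref[ri + k]:
                    match_run += 1
                else:
                    nm += 1
                    md_parts.append(str(match_run))
                    md_parts.append(ref[ri + k])
                    match_run = 0
            qi += ln
            ri += ln
        elif op == "I":
            nm += ln
            qi += ln
        elif op in ("D", "N"):
            if op == "D":
                nm += ln
                md_parts.append(str(match_run))
                md_parts.append("^" + ref[ri:ri + ln])
                match_run = 0
            ri += ln
    md_parts.append(str(match_run))
    rec.set_tag("NM", nm, "i")
    rec.set_tag("MD", "".join(md_parts), "Z")
    return rec


def realign_local(rec: pysam.AlignedSegment, reference,
                  preset: ScoringPreset, pad: int = 20) -> pysam.AlignedSegment:
    """Refine a lifted alignment with an affine-gap DP against a local window.

    The aligned core (soft clips excluded) is realigned against the lifted
    span padded by ``pad`` bp on each side (clamped to the contig).  The
    refined CIGAR replaces the old one only if it scores strictly higher
    under the preset; AS is set to the resulting score either way.
    """
    if rec.is_unmapped or rec.query_sequence is None:
        return rec
    runs = runs_from_cigartuples(rec.cigartuples)
    head_runs = []
    tail_runs = []
    core = runs[:]
    while core and core[0][0] in ("H", "S"):
        head_runs.append(core.pop(0))
    while core and core[-1][0] in ("H", "S"):
        tail_runs.insert(0, core.pop())
    head_soft = sum(ln for op, ln in head_runs if op == "S")
    tail_soft = sum(ln for op, ln in tail_runs if op == "S")
    seq = rec.query_sequence.upper()
    core_seq = seq[head_soft: len(seq) - tail_soft if tail_soft else len(seq)]
    if not core_seq:
        return rec
    span = reference_span(core)
    contig_len = rec.header.get_reference_length(rec.reference_name)
    win_lo = max(0, rec.reference_start - pad)
    win_hi = min(contig_len, rec.reference_start + span + pad)
    window = _fetch(reference, rec.reference_name, win_lo, win_hi)

    cur_ref = window[rec.reference_start - win_lo:
                     rec.reference_start - win_lo + span]
    cur_score = score_alignment(core, core_seq, cur_ref, preset)
    new_score, new_runs, ref_off = affine_fit_align(core_seq, window, preset)
    if new_score > cur_score:
        rec.cigartuples = runs_to_cigartuples(
            merge_runs(head_runs + new_runs + tail_runs))
        rec.reference_start = win_lo + ref_off
        rec.set_tag("AS", int(new_score), "i")
    else:
        rec.set_tag("AS", int(cur_score), "i")
    return rec
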