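"""Collate deferred pairs and reconcile lifted vs re-mapped alignments.

``collate`` makes the deferred read set properly paired: deferred ends are
streamed into a pair of hash maps (first-of-pair / second-of-pair); names
completing a pair are emitted immediately, and mates of the remaining
singletons are pulled out of the committed stream so re-mapping can run in
paired-end mode.

``reconcile`` compares, per read name and end, the lifted alignment with
the re-mapped one and keeps the higher-confidence candidate: lower edit
distance (NM) wins; ties go to higher MAPQ; remaining ties are broken by a
seeded pseudo-random draw keyed on the read name, so the outcome is
deterministic and independent of processing order.  A mapped candidate
always beats an unmapped one.
"""

from __future__ import annotations

import logging
import random
import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import pysam

logger = logging.getLogger(__name__)


class CollateError(ValueError):
    pass


def _end_of(rec: pysam.AlignedSegment) -> int:
    if not rec.is_paired or rec.is_read1:
        return 1
    return 2


def collate(deferred: Iterable[pysam.AlignedSegment],
            committed: Iterable[pysam.AlignedSegment]):
    """Return (paired_deferred, updated_committed, singletons).

    ``paired_deferred`` contains every deferred record plus the committed
    mates of deferred singletons; ``updated_committed`` is the committed
    stream minus those moved mates.  Unpaired (single-end) deferred records
    pass straight through.  ``singletons`` lists records whose mate was
    found in neither stream (also appended to ``paired_deferred``, with a
    warning).
    """
    first: dict[str, pysam.AlignedSegment] = {}
    second: dict[str, pysam.AlignedSegment] = {}
    paired_out: list[pysam.AlignedSegment] = []
    for rec in deferred:
        if not rec.is_paired:
            paired_out.append(rec)
            continue
        mine, other = (first, second) if _end_of(rec) == 1 else (second, first)
        name = rec.query_name
        if name in mine:
            raise CollateError(
                f"read {name!r} seen twice with the same pair flag")
        mate = other.pop(name, None)
        if mate is not None:
            if _end_of(rec) == 1:
                paired_out.extend([rec, mate])
            else:
                paired_out.extend([mate, rec])
        else:
            mine[name] = rec

    committed_out: list[pysam.AlignedSegment] = []
    for rec in committed:
        if not rec.is_paired:
            committed_out.append(rec)
            continue
        name = rec.query_name
        other = second if _end_of(rec) == 1 else first
        mate = other.pop(name, None)
        if mate is not None:
            if _end_of(rec) == 1:
                paired_out.extend([rec, mate])
            else:
                paired_out.extend([mate, rec])
        else:
            committed_out.append(rec)

    singles = list(first.values()) + list(second.values())
    for rec in singles:
        logger.warning("deferred singleton %s has no mate in either stream",
                       rec.query_name)
        paired_out.append(rec)
    return paired_out, committed_out, singles


@dataclass(frozen=True)
class ReconcileDecision:
    chosen: str      # "lifted" or "remapped"
    criterion: str   # "only_candidate", "mapped", "edit_distance", "mapq", "random"


def _nm(rec: pysam.AlignedSegment, reference=None) -> int | None:
    if rec.is_unmapped:
        return None
    if rec.has_tag("NM"):
        return int(rec.get_tag("NM"))
    if reference is not None:
        from .engine import recompute_nm_md
        recompute_nm_md(rec, reference)
        return int(rec.get_tag("NM"))
    return None


def _tie_break_rng(seed: int, name: str, end: int) -> random.Random:
    # crc32 keying keeps the draw stable across runs and processing orders
    key = zlib.crc32(f"{name}/{end}".encode()) ^ (seed & 0xFFFFFFFF)
    return random.Random(key)


def reconcile_pairwise(lifted: pysam.AlignedSegment | None,
                       remapped: pysam.AlignedSegment | None,
                       seed: int = 0,
                       reference=None) -> tuple[pysam.AlignedSegment, ReconcileDecision]:
    """Choose between one lifted and one re-mapped candidate for a read end."""
    if lifted is None or remapped is None:
        rec = lifted if remapped is None else remapped
        which = "lifted" if remapped is None else "remapped"
        return rec, ReconcileDecision(which, "only_candidate")
    lm, rm = not lifted.is_unmapped, not remapped.is_unmapped
    if lm != rm:
        return ((lifted, ReconcileDecision("lifted", "mapped")) if lm
                else (remapped, ReconcileDecision("remapped", "mapped")))
    if not lm:
        return lifted, ReconcileDecision("lifted", "mapped")
    nm_l, nm_r = _nm(lifted, reference), _nm(remapped, reference)
    if nm_l is not None and nm_r is not None and nm_l != nm_r:
        return ((lifted, ReconcileDecision("lifted", "edit_distance"))
                if nm_l < nm_r
                else (remapped, ReconcileDecision("remapped", "edit_distance")))
    if lifted.mapping_quality != remapped.mapping_quality:
        return ((lifted, ReconcileDecision("lifted", "mapq"))
                if lifted.mapping_quality > remapped.mapping_quality
                else (remapped, ReconcileDecision("remapped", "mapq")))
    rng = _tie_break_rng(seed, lifted.query_name, _end_of(lifted))
    if rng.random() < 0.5:
        return lifted, ReconcileDecision("lifted", "random")
    return remapped, ReconcileDecision("remapped", "random")


def reconcile(lifted: Sequence[pysam.AlignedSegment],
              remapped: Sequence[pysam.AlignedSegment],
              seed: int = 0,
              reference=None):
    """Reconcile two name-grouped deferred sets; returns (records, decisions).

    Ends are compared independently; a name/end present in only one input
    passes through unchanged.
    """
    def keyed(records):
        d: dict[tuple[str, int], pysam.AlignedSegment] = {}
        for rec in records:
            if rec.is_secondary or rec.is_supplementary:
                continue
            key = (rec.query_name, _end_of(rec))
            if key in d:
                raise CollateError(f"duplicate primary record for {key}")
            d[key] = rec
        return d

    by_l, by_r = keyed(lifted), keyed(remapped)
    out: list[pysam.AlignedSegment] = []
    decisions: dict[tuple[str, int], ReconcileDecision] = {}
    for key in sorted(set(by_l) | set(by_r)):
        rec, dec = reconcile_pairwise(by_l.get(key), by_r.get(key),
                                      seed=seed, reference=reference)
        out.append(rec)
        decisions[key] = dec
    return out, decisions


def merge_final(committed: Sequence[pysam.AlignedSegment],
                reconciled: Sequence[pysam.AlignedSegment]):
    """Merge and coordinate-sort the committed and reconciled record sets.

    Sort key is (contig index, position, name, flag); unmapped records sort
    last.  The output multiset is exactly the union of the inputs.
    """
    def key(rec: pysam.AlignedSegment):
        tid = rec.reference_id if rec.reference_id >= 0 else 1 << 30
        pos = rec.reference_start if not rec.is_unmapped else 1 << 40
        return (tid, pos, rec.query_name, rec.flag)

    return sorted(list(committed) + list(reconciled), key=key)


def write_bam(path: str, records: Iterable[pysam.AlignedSegment],
              header: pysam.AlignmentHeader, sort_order: str = "coordinate",
              make_index: bool = False) -> None:
    hd = header.to_dict()
    hd.setdefault("HD", {"VN": "1.6"})
    hd["HD"]["SO"] = sort_order
    mode = "w" if str(path).endswith(".sam") else "wb"
    with pysam.AlignmentFile(path, mode, header=pysam.AlignmentHeader.from_dict(hd)) as fh:
        for rec in records:
            fh.write(rec)
    if make_index and mode == "wb" and sort_order == "coordinate":
        pysam.index(str(path))
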