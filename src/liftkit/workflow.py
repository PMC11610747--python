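"""End-to-end selective lift-over pipeline.

Implements the full workflow: lift every record, classify into
committed / deferred / suppressed, collate deferred pairs, re-map the
deferred set with a pluggable mapper, reconcile lifted vs re-mapped
candidates, and merge into the final coordinate-sorted output plus a
source-coordinate suppressed stream and a JSON report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from .chain import ChainIndex, parse_chain
from .engine import (
    LiftResult,
    lift_alignment,
    make_source_header,
    make_target_header,
    recompute_nm_md,
    realign_local,
    reverse_complement,
    update_mate_and_tlen,
)
from .pair_ops import collate, merge_final, reconcile, write_bam
from .selector import (
    LiftabilityAnnotation,
    SelectionPolicy,
    load_policy,
    load_scoring,
    split_streams,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    chain_path: str | None = None
    index_path: str | None = None
    input_bam: str | None = None
    target_fasta: str | None = None
    annotation_bed: str | None = None
    preset: str = "bwa-mem"
    allowed_gap: int = 0
    realign: bool = False
    realign_pad: int = 20
    seed: int = 0
    threads: int = 1
    out_prefix: str = "liftkit_out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    n_input_primary: int = 0
    n_committed: int = 0
    n_deferred: int = 0
    n_suppressed: int = 0
    n_reconciled_lifted: int = 0
    n_reconciled_remapped: int = 0
    defer_reasons: dict = field(default_factory=dict)
    suppress_reasons: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_index(cfg: RunConfig) -> ChainIndex:
    if cfg.index_path:
        idx = ChainIndex.load(cfg.index_path)
        idx.allowed_gap = cfg.allowed_gap
        return idx
    if cfg.chain_path:
        chains = parse_chain(cfg.chain_path)
        return ChainIndex(chains, allowed_gap=cfg.allowed_gap)
    raise ValueError("RunConfig needs chain_path or index_path")


def lift_records(records, idx: ChainIndex, target_header=None,
                 reference=None, realign=False, scoring=None,
                 realign_pad: int = 20, recompute_tags=True):
    """Lift an iterable of records; yields LiftResult per record.

    When ``reference`` (target genome) is given, NM/MD are recomputed on
    every lifted record; with ``realign=True`` a localized DP refinement
    runs first.
    """
    if target_header is None:
        target_header = make_target_header(idx)
    for rec in records:
        res = lift_alignment(rec, idx, target_header)
        if res.lifted and not res.record.is_unmapped and reference is not None:
            if realign and scoring is not None:
                realign_local(res.record, reference, scoring, pad=realign_pad)
            if recompute_tags:
                recompute_nm_md(res.record, reference)
        yield res


def _pair_up(results: list[LiftResult]) -> None:
    """Refresh mate fields of lifted pairs (both ends lifted and mapped)."""
    by_name: dict[str, dict[int, LiftResult]] = {}
    for res in results:
        rec = res.source_record
        if not rec.is_paired or rec.is_secondary or rec.is_supplementary:
            continue
        end = 1 if rec.is_read1 else 2
        by_name.setdefault(rec.query_name, {})[end] = res
    for name, ends in by_name.items():
        if len(ends) == 2 and ends[1].lifted and ends[2].lifted:
            update_mate_and_tlen(ends[1].record, ends[2].record)


def _read_seq_for_remap(rec: pysam.AlignedSegment) -> tuple[str, str | None]:
    """Original read sequence/quality (undo reverse-strand storage)."""
    seq = rec.query_sequence or ""
    qual = rec.query_qualities
    if rec.is_reverse:
        seq = reverse_complement(seq)
        qual = qual[::-1] if qual is not None else None
    return seq, qual


def remap_deferred(paired_deferred, target_genome: dict[str, str],
                   target_header, mapper=None):
    """Re-map the collated deferred set with the built-in naive mapper."""
    from .mapper import NaiveMapper
    if mapper is None:
        mapper = NaiveMapper(target_genome)
    by_name: dict[str, dict[int, pysam.AlignedSegment]] = {}
    singles = []
    order: list[str] = []
    for rec in paired_deferred:
        if not rec.is_paired:
            singles.append(rec)
            continue
        if rec.query_name not in by_name:
            order.append(rec.query_name)
        by_name.setdefault(rec.query_name, {})[1 if rec.is_read1 else 2] = rec
    out = []
    for name in order:
        ends = by_name[name]
        if len(ends) == 2:
            s1, q1 = _read_seq_for_remap(ends[1])
            s2, q2 = _read_seq_for_remap(ends[2])
            r1, r2 = mapper.map_pair(name, s1, s2, q1, q2, header=target_header)
            out.extend([r1, r2])
        else:
            (end, rec), = ends.items()
            seq, qual = _read_seq_for_remap(rec)
            r = mapper.map_read(name, seq, qual, header=target_header)
            r.is_paired = True
            r.is_read1 = end == 1
            r.is_read2 = end == 2
            out.append(r)
    for rec in singles:
        seq, qual = _read_seq_for_remap(rec)
        out.append(mapper.map_read(rec.query_name, seq, qual, header=target_header))
    return out


def run_pipeline(cfg: RunConfig,
                 idx: ChainIndex | None = None,
                 records=None,
                 target_genome: dict[str, str] | None = None,
                 annotation: LiftabilityAnnotation | None = None,
                 policy: SelectionPolicy | None = None,
                 remapper=None,
                 write_outputs: bool = True):
    """Execute lift -> classify -> collate -> re-map -> reconcile -> merge.

    Inputs may be passed in memory (``idx``, ``records``, ``target_genome``)
    or read from the paths in ``cfg``.  Returns (final_records,
    suppressed_records, report); when ``write_outputs`` is true the final
    BAM/SAM, suppressed stream, and JSON report are written under
    ``cfg.out_prefix``.
    """
    if idx is None:
        idx = load_index(cfg)
    if records is None:
        if not cfg.input_bam:
            raise ValueError("no input records")
        with pysam.AlignmentFile(cfg.input_bam, check_sq=False) as fh:
            bam_contigs = {fh.get_reference_name(i): fh.get_reference_length(
                fh.get_reference_name(i)) for i in range(fh.nreferences)}
            missing = [c for c in idx.source_contigs
                       if c in bam_contigs and bam_contigs[c] != idx.source_lengths[c]]
            if missing:
                raise ValueError(
                    f"contig length mismatch between chain and BAM: {missing}")
            records = [r for r in fh]
    else:
        records = list(records)
    if target_genome is None:
        if cfg.target_fasta:
            from .synth import read_fasta
            target_genome = read_fasta(cfg.target_fasta)
        else:
            raise ValueError("no target genome")
    if annotation is None and cfg.annotation_bed:
        annotation = LiftabilityAnnotation.from_bed(cfg.annotation_bed)
    if policy is None:
        policy = load_policy(cfg.preset)
    scoring = load_scoring(cfg.preset) if cfg.realign else None

    target_header = make_target_header(idx)
    source_header = make_source_header(idx)

    primaries = [r for r in records if not (r.is_secondary or r.is_supplementary)]
    results = list(lift_records(
        primaries, idx, target_header, reference=target_genome,
        realign=cfg.realign, scoring=scoring, realign_pad=cfg.realign_pad))
    _pair_up(results)

    committed, deferred, suppressed, decisions = split_streams(
        results, annotation, policy)

    report = RunReport(config=cfg.to_dict())
    report.n_input_primary = len(primaries)
    report.n_committed = len(committed)
    report.n_deferred = len(deferred)
    report.n_suppressed = len(suppressed)
    for dec in decisions:
        bucket = (report.defer_reasons if dec.group == "deferred"
                  else report.suppress_reasons if dec.group == "suppressed"
                  else None)
        if bucket is not None:
            for r in dec.reasons:
                bucket[r] = bucket.get(r, 0) + 1

    paired_deferred, committed_kept, _ = collate(deferred, committed)
    remapped = (remapper(paired_deferred, target_genome, target_header)
                if remapper is not None
                else remap_deferred(paired_deferred, target_genome, target_header))
    reconciled, rdec = reconcile(paired_deferred, remapped, seed=cfg.seed,
                                 reference=target_genome)
    for dec in rdec.values():
        if dec.chosen == "lifted":
            report.n_reconciled_lifted += 1
        else:
            report.n_reconciled_remapped += 1

    final = merge_final(committed_kept, reconciled)

    if write_outputs:
        prefix = Path(cfg.out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        suffix = ".sam"
        write_bam(f"{prefix}-final{suffix}", final, target_header,
                  sort_order="coordinate")
        write_bam(f"{prefix}-suppressed{suffix}", suppressed, source_header,
                  sort_order="unsorted")
        with open(f"{prefix}-report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    return final, suppressed, report


def lift_only(records, idx: ChainIndex, target_genome=None):
    """Baseline: lift everything, no selection or re-mapping."""
    target_header = make_target_header(idx)
    out = []
    unliftable = []
    for res in lift_records(records, idx, target_header, reference=target_genome):
        if res.lifted:
            out.append(res.record)
        else:
            unliftable.append(res.source_record)
    return out, unliftable
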