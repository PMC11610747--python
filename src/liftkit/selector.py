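"""Commit / defer / suppress classification of lifted reads.

Each lifted primary record is placed in exactly one of three groups:

* **suppressed** — the mapping has no trustworthy counterpart on the target:
  either the lift itself failed (source-specific sequence) or the source
  position overlaps an annotated "unliftable" region.  Suppressed records
  are emitted in source coordinates so source-unique regions stay
  analyzable.
* **deferred** — the lift succeeded but is low-confidence (lifted into a
  mappability-reduced target region, or an alignment feature breaches its
  threshold); deferred reads are re-mapped and later reconciled.
* **committed** — everything else; the lifted record is final.

Deferral triggers disjunctively: a read is deferred if ANY enabled feature
fails its threshold (MAPQ below ``mapq_min``, alignment score below
``aln_score_min``, clipped fraction above ``clip_frac_max``, edit distance
above ``nm_max``, fragment length outside ``frag_len_range``).
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from typing import Iterable

import pysam
import yaml
from intervaltree import IntervalTree

from .engine import LiftResult

logger = logging.getLogger(__name__)

UNLIFTABLE = "unliftable"
MAPPABILITY_REDUCED = "mappability_reduced"
GROUPS = ("committed", "deferred", "suppressed")


class LiftabilityAnnotation:
    """Labeled genomic intervals driving suppress/defer decisions.

    "unliftable" intervals are in source coordinates, "mappability_reduced"
    intervals in target coordinates; both half-open.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int, str]] = ()):
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for contig, start, end, label in intervals:
            self.add(contig, start, end, label)

    def add(self, contig: str, start: int, end: int, label: str) -> None:
        if label not in (UNLIFTABLE, MAPPABILITY_REDUCED):
            raise ValueError(f"unknown label {label!r}")
        if end <= start:
            raise ValueError("empty interval")
        self._trees.setdefault((label, contig), IntervalTree()).addi(start, end)

    def overlaps(self, label: str, contig: str, start: int, end: int) -> bool:
        tree = self._trees.get((label, contig))
        return bool(tree is not None and tree.overlap(start, end))

    def intervals(self) -> list[tuple[str, int, int, str]]:
        out = []
        for (label, contig), tree in self._trees.items():
            merged = tree.copy()
            merged.merge_overlaps(strict=False)
            for iv in merged:
                out.append((contig, iv.begin, iv.end, label))
        out.sort()
        return out

    # -- BED I/O (4-column; label in the name field) ----------------------

    @classmethod
    def from_bed(cls, path: str) -> "LiftabilityAnnotation":
        ann = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ValueError(f"{path}:{lineno}: need 4 BED columns")
                ann.add(parts[0], int(parts[1]), int(parts[2]), parts[3])
        return ann

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for contig, start, end, label in self.intervals():
                fh.write(f"{contig}\t{start}\t{end}\t{label}\n")


@dataclass(frozen=True)
class SelectionPolicy:
    """Per-aligner thresholds for the commit/defer decision."""

    name: str = "default"
    mapq_min: int | None = None
    aln_score_min: int | None = None
    clip_frac_max: float | None = 0.05
    nm_max: int | None = None
    frag_len_range: tuple[int, int] | None = None

    @classmethod
    def from_dict(cls, d: dict, name: str = "custom") -> "SelectionPolicy":
        rng = d.get("frag_len_range")
        return cls(
            name=d.get("name", name),
            mapq_min=d.get("mapq_min"),
            aln_score_min=d.get("aln_score_min"),
            clip_frac_max=d.get("clip_frac_max", 0.05),
            nm_max=d.get("nm_max"),
            frag_len_range=tuple(rng) if rng else None,
        )

    @classmethod
    def from_yaml(cls, path: str) -> "SelectionPolicy":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        sel = doc.get("selection", doc)
        return cls.from_dict(sel, name=doc.get("name", "custom"))

    def to_yaml_dict(self) -> dict:
        return {
            "name": self.name,
            "selection": {
                k: v for k, v in (
                    ("mapq_min", self.mapq_min),
                    ("aln_score_min", self.aln_score_min),
                    ("clip_frac_max", self.clip_frac_max),
                    ("nm_max", self.nm_max),
                    ("frag_len_range",
                     list(self.frag_len_range) if self.frag_len_range else None),
                ) if v is not None
            },
        }


def _preset_doc(name: str) -> dict:
    res = importlib.resources.files("liftkit") / "presets" / f"{name}.yaml"
    if not res.is_file():
        raise KeyError(f"no preset named {name!r}")
    return yaml.safe_load(res.read_text())


def load_policy(preset: str) -> SelectionPolicy:
    """Load a shipped selection preset (``bwa-mem``, ``bowtie2``, ``minimap2``)."""
    doc = _preset_doc(preset)
    return SelectionPolicy.from_dict(doc["selection"], name=doc["name"])


def load_scoring(preset: str):
    """Load a shipped realignment scoring preset."""
    from .realign import ScoringPreset
    doc = _preset_doc(preset)
    return ScoringPreset(name=doc["name"], **doc["scoring"])


@dataclass(frozen=True)
class SelectionDecision:
    group: str
    reasons: tuple[str, ...] = ()


_warned_missing_as = False


def classify_record(result: LiftResult,
                    ann: LiftabilityAnnotation | None,
                    pol: SelectionPolicy) -> SelectionDecision:
    """Assign one lifted (or unliftable) primary record to a group."""
    global _warned_missing_as
    src = result.source_record

    if not result.lifted:
        return SelectionDecision("suppressed", (result.reason or "unliftable",))
    if (ann is not None and not src.is_unmapped
            and ann.overlaps(UNLIFTABLE, src.reference_name,
                             src.reference_start, src.reference_end or
                             src.reference_start + 1)):
        return SelectionDecision("suppressed", ("unliftable_region",))

    rec = result.record
    if rec.is_unmapped:
        return SelectionDecision("deferred", ("unmapped",))

    reasons: list[str] = []
    if (ann is not None
            and ann.overlaps(MAPPABILITY_REDUCED, rec.reference_name,
                             rec.reference_start, rec.reference_end)):
        reasons.append("mappability_reduced")
    if pol.mapq_min is not None and rec.mapping_quality < pol.mapq_min:
        reasons.append("mapq")
    if pol.aln_score_min is not None:
        if rec.has_tag("AS"):
            if rec.get_tag("AS") < pol.aln_score_min:
                reasons.append("aln_score")
        elif not _warned_missing_as:
            logger.warning("AS tag absent; alignment-score threshold skipped")
            _warned_missing_as = True
    if pol.clip_frac_max is not None:
        qlen = rec.infer_read_length() or 0
        clipped = sum(ln for op, ln in (rec.cigartuples or [])
                      if op in (4, 5))  # S, H
        if qlen and clipped / qlen > pol.clip_frac_max:
            reasons.append("clipping")
    if pol.nm_max is not None and rec.has_tag("NM") and rec.get_tag("NM") > pol.nm_max:
        reasons.append("edit_distance")
    if pol.frag_len_range is not None and rec.is_paired and rec.is_proper_pair:
        tlen = abs(rec.template_length)
        if tlen and not pol.frag_len_range[0] <= tlen <= pol.frag_len_range[1]:
            reasons.append("fragment_length")
    if reasons:
        return SelectionDecision("deferred", tuple(reasons))
    return SelectionDecision("committed", ())


def split_streams(results: Iterable[LiftResult],
                  ann: LiftabilityAnnotation | None,
                  pol: SelectionPolicy):
    """Partition lift results into (committed, deferred, suppressed) lists.

    Committed and deferred lists hold lifted (target-coordinate) records;
    the suppressed list holds the original source-coordinate records.
    Decisions are independent per record, so any partitioning of the input
    yields the same assignment; output order follows input order.
    """
    committed: list[pysam.AlignedSegment] = []
    deferred: list[pysam.AlignedSegment] = []
    suppressed: list[pysam.AlignedSegment] = []
    decisions: list[SelectionDecision] = []
    for res in results:
        dec = classify_record(res, ann, pol)
        decisions.append(dec)
        if dec.group == "suppressed":
            suppressed.append(res.source_record)
        elif dec.group == "deferred":
            deferred.append(res.record)
        else:
            committed.append(res.record)
    return committed, deferred, suppressed, decisions


def write_stream(path: str, records: Iterable[pysam.AlignedSegment],
                 header: pysam.AlignmentHeader) -> None:
    """Write records to SAM (.sam) or BAM (anything else)."""
    mode = "w" if str(path).endswith(".sam") else "wb"
    with pysam.AlignmentFile(path, mode, header=header) as fh:
        for rec in records:
            fh.write(rec)
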