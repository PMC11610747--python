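"""Full record lifting: position, strand, CIGAR, tags, mates, realignment."""

import numpy as np
import pysam
import pytest

from liftkit.chain import ChainIndex, parse_chain
from liftkit.cigar import query_length, runs_from_cigartuples
from liftkit.engine import (
    lift_alignment,
    make_target_header,
    realign_local,
    recompute_nm_md,
    reverse_complement,
    update_mate_and_tlen,
)
from liftkit.mapper import NaiveMapper
from liftkit.realign import DEFAULT_PRESETS, affine_fit_align, score_alignment
from liftkit.synth import emit_chain, generate_genome_pair, simulate_reads

from conftest import make_header, make_record
from oracles import affine_dp_score, aligned_pairs_from_runs, expected_target_pairing


IDENTITY = "chain 10 src 5000 + 0 5000 tgt 5000 + 0 5000 1\n5000\n\n"


def test_identity_chain_lift_is_noop():
    idx = ChainIndex(parse_chain(IDENTITY))
    th = make_target_header(idx)
    sh = make_header({"src": 5000})
    rec = make_record(sh, contig="src", pos=1000, cigar="50M", seq="A" * 50,
                      tags=[("NM", 0), ("XY", "keep")])
    res = lift_alignment(rec, idx, th)
    assert res.lifted
    out = res.record
    assert (out.reference_name, out.reference_start) == ("tgt", 1000)
    assert out.cigarstring == "50M"
    assert out.query_sequence == rec.query_sequence
    assert out.get_tag("XY") == "keep"         # unrecognized tags preserved


def test_lift_across_dsource_gap_keeps_nm_as_until_recompute():
    txt = "chain 10 src 1000 + 0 100 tgt 1000 + 500 598 1\n40 2 0\n58\n\n"
    idx = ChainIndex(parse_chain(txt))
    sh = make_header({"src": 1000})
    rec = make_record(sh, contig="src", pos=30, cigar="20M", seq="A" * 20,
                      tags=[("NM", 0), ("AS", 20)])
    res = lift_alignment(rec, idx, make_target_header(idx))
    assert res.record.cigarstring == "10M2I8M"
    assert res.record.reference_start == 530
    assert res.gaps_crossed == 1
    assert res.record.get_tag("NM") == 0 and res.record.get_tag("AS") == 20


def test_read_in_nonchain_region_unliftable():
    txt = "chain 10 src 1000 + 0 100 tgt 1000 + 0 100 1\n100\n\n"
    idx = ChainIndex(parse_chain(txt))
    sh = make_header({"src": 1000})
    rec = make_record(sh, contig="src", pos=500, cigar="50M", seq="A" * 50)
    res = lift_alignment(rec, idx, make_target_header(idx))
    assert not res.lifted and res.reason == "no_covering_interval"


def test_minus_strand_lift_reverse_complements():
    # source [100,200) -> target forward [700,800), inverted
    txt = "chain 10 src 1000 + 100 200 tgt 1000 - 200 300 1\n100\n\n"
    idx = ChainIndex(parse_chain(txt))
    sh = make_header({"src": 1000})
    seq = "ACGTACGTTA" * 2
    rec = make_record(sh, contig="src", pos=120, cigar="20M", seq=seq)
    res = lift_alignment(rec, idx, make_target_header(idx))
    out = res.record
    assert res.strand_flipped and out.is_reverse
    # source span [120,140) maps to forward target [760,780)
    assert out.reference_start == 760
    assert out.query_sequence == reverse_complement(seq)
    assert out.cigarstring == "20M"


def test_unmapped_record_passes_through_with_translated_placement():
    idx = ChainIndex(parse_chain(IDENTITY))
    sh = make_header({"src": 5000})
    rec = make_record(sh, contig=None, seq="A" * 10, flag=0x4)
    rec.reference_id = 0
    rec.reference_start = 42
    res = lift_alignment(rec, idx, make_target_header(idx))
    assert res.lifted and res.record.is_unmapped
    assert res.record.reference_start == 42


# ---------------------------------------------------------------------------
# mate fields / TLEN
# ---------------------------------------------------------------------------


def test_mate_and_tlen_same_contig():
    h = make_header({"t": 10_000})
    r1 = make_record(h, name="p", contig="t", pos=100, cigar="50M", seq="A" * 50,
                     flag=0x1 | 0x40)
    r2 = make_record(h, name="p", contig="t", pos=300, cigar="50M", seq="A" * 50,
                     flag=0x1 | 0x80 | 0x10)
    update_mate_and_tlen(r1, r2)
    assert r1.template_length == 250 and r2.template_length == -250
    assert r1.next_reference_start == 300 and r2.next_reference_start == 100
    assert r1.is_proper_pair and r2.is_proper_pair


def test_mate_on_different_contigs_clears_proper_pair():
    h = make_header({"a": 1000, "b": 1000})
    r1 = make_record(h, name="p", contig="a", pos=10, cigar="10M", seq="A" * 10,
                     flag=0x1 | 0x40 | 0x2)
    r2 = make_record(h, name="p", contig="b", pos=20, cigar="10M", seq="A" * 10,
                     flag=0x1 | 0x80 | 0x10)
    update_mate_and_tlen(r1, r2)
    assert not r1.is_proper_pair and not r2.is_proper_pair
    assert r1.next_reference_name == "b"
    assert r1.template_length == 0


def test_unmapped_mate_flags():
    h = make_header({"a": 1000})
    r1 = make_record(h, name="p", contig="a", pos=10, cigar="10M", seq="A" * 10,
                     flag=0x1 | 0x40)
    r2 = make_record(h, name="p", contig=None, seq="A" * 10, flag=0x1 | 0x80 | 0x4)
    update_mate_and_tlen(r1, r2)
    assert r1.mate_is_unmapped and not r2.mate_is_unmapped
    assert r1.template_length == 0


# ---------------------------------------------------------------------------
# NM / MD
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def ref50():
    rng = np.random.default_rng(9)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=200))
    return {"t": seq}


def test_nm_md_perfect_match(ref50):
    h = make_header({"t": 200})
    rec = make_record(h, contig="t", pos=0, cigar="50M", seq=ref50["t"][:50])
    recompute_nm_md(rec, ref50)
    assert rec.get_tag("NM") == 0 and rec.get_tag("MD") == "50"


def test_nm_md_single_mismatch(ref50):
    h = make_header({"t": 200})
    seq = list(ref50["t"][:20])
    orig = seq[10]
    seq[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[orig]
    rec = make_record(h, contig="t", pos=0, cigar="20M", seq="".join(seq))
    recompute_nm_md(rec, ref50)
    assert rec.get_tag("NM") == 1
    assert rec.get_tag("MD") == f"10{orig}9"


def test_nm_md_deletion(ref50):
    h = make_header({"t": 200})
    seq = ref50["t"][:5] + ref50["t"][7:12]
    rec = make_record(h, contig="t", pos=0, cigar="5M2D5M", seq=seq)
    recompute_nm_md(rec, ref50)
    assert rec.get_tag("NM") == 2
    assert rec.get_tag("MD") == f"5^{ref50['t'][5:7]}5"


def test_nm_md_idempotent_and_insertion(ref50):
    h = make_header({"t": 200})
    seq = ref50["t"][:10] + "AC" + ref50["t"][10:20]
    rec = make_record(h, contig="t", pos=0, cigar="10M2I10M", seq=seq)
    recompute_nm_md(rec, ref50)
    first = (rec.get_tag("NM"), rec.get_tag("MD"))
    recompute_nm_md(rec, ref50)
    assert first == (rec.get_tag("NM"), rec.get_tag("MD")) == (2, "20")


# ---------------------------------------------------------------------------
# realignment
# ---------------------------------------------------------------------------


def test_realign_already_optimal_unchanged(ref50):
    h = make_header({"t": 200})
    rec = make_record(h, contig="t", pos=10, cigar="40M", seq=ref50["t"][10:50])
    realign_local(rec, ref50, DEFAULT_PRESETS["bwa-mem"])
    assert rec.cigarstring == "40M" and rec.reference_start == 10
    assert rec.get_tag("AS") == 40


def test_realign_collapses_cancelling_indels(ref50):
    h = make_header({"t": 200})
    rec = make_record(h, contig="t", pos=0, cigar="8M2I2D10M", seq=ref50["t"][:20])
    preset = DEFAULT_PRESETS["bwa-mem"]
    before = score_alignment(runs_from_cigartuples(rec.cigartuples),
                             rec.query_sequence, ref50["t"][:22], preset)
    realign_local(rec, ref50, preset)
    assert rec.cigarstring == "20M"
    assert rec.get_tag("AS") == 20 > before


def test_realign_score_matches_independent_dp_oracle():
    """Optimal fit-alignment scores equal a from-scratch DP on random reads."""
    rng = np.random.default_rng(31)
    preset = DEFAULT_PRESETS["bwa-mem"]
    genome = "".join("ACGT"[i] for i in rng.integers(0, 4, size=3000))
    ref = {"t": genome}
    h = make_header({"t": len(genome)})
    n_checked = 0
    for _ in range(60):
        start = int(rng.integers(0, len(genome) - 120))
        read = list(genome[start:start + 100])
        # random mutations
        for _ in range(int(rng.integers(0, 6))):
            p = int(rng.integers(0, len(read)))
            r = rng.random()
            if r < 0.5:
                read[p] = "ACGT"[int(rng.integers(0, 4))]
            elif r < 0.75:
                read.insert(p, "ACGT"[int(rng.integers(0, 4))])
            else:
                del read[p]
        seq = "".join(read)
        rec = make_record(h, contig="t", pos=start, cigar=f"{len(seq)}M", seq=seq)
        realign_local(rec, ref, preset, pad=20)
        win_lo = max(0, start - 20)
        win_hi = min(len(genome), start + len(seq) + 20)
        expect = affine_dp_score(seq, genome[win_lo:win_hi], preset.match,
                                 preset.mismatch, preset.gap_open,
                                 preset.gap_extend)
        assert rec.get_tag("AS") >= expect  # window may differ; never worse...
        score, _, _ = affine_fit_align(seq, genome[win_lo:win_hi], preset)
        assert score == expect
        n_checked += 1
    assert n_checked == 60


# ---------------------------------------------------------------------------
# base-level pairing against the correspondence-map oracle
# ---------------------------------------------------------------------------


def test_lifted_base_pairing_matches_correspondence_oracle(genome_pair, chain_index):
    reads, truth = simulate_reads(genome_pair.source, 250, seed=13,
                                  err_rate=0.0, name_prefix="src")
    sh = make_header({c: len(s) for c, s in genome_pair.source.items()})
    th = make_target_header(chain_index)
    n_lifted = 0
    for pair in reads:
        for end, (seq, t) in enumerate([(pair.seq1, pair.truth1),
                                        (pair.seq2, pair.truth2)], start=1):
            stored = seq if t.strand == "+" else reverse_complement(seq)
            rec = make_record(sh, name=f"{pair.name}/{end}", contig=t.contig,
                              pos=t.pos, cigar=f"{len(seq)}M", seq=stored,
                              flag=0x10 if t.strand == "-" else 0)
            res = lift_alignment(rec, chain_index, th)
            if not res.lifted:
                # only legitimate for reads not wholly inside one aligned
                # block (uncovered bases, or straddling a chain boundary)
                blocks = genome_pair.cmap.blocks
                inside_one = any(
                    b.source_start <= t.pos and t.pos + len(seq) <= b.source_end
                    for b in blocks)
                assert not inside_one
                continue
            n_lifted += 1
            got = dict(aligned_pairs_from_runs(
                runs_from_cigartuples(res.record.cigartuples),
                res.record.reference_start))
            expect = expected_target_pairing(
                runs_from_cigartuples(rec.cigartuples), rec.reference_start,
                genome_pair.cmap, len(seq), res.strand_flipped)
            assert got == expect
            assert query_length(runs_from_cigartuples(res.record.cigartuples)) == len(seq)
    assert n_lifted > 400
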