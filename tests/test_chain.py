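"""Chain parsing, rank bit vectors, and point lift queries."""

import numpy as np
import pytest

from liftkit.chain import (
    Chain,
    ChainGap,
    ChainIndex,
    ChainParseError,
    ChainValidationError,
    RankBitVector,
    parse_chain,
)
from liftkit.synth import emit_chain, generate_genome_pair

from oracles import brute_rank, linear_scan_lift


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def test_parse_single_block_chain():
    txt = "chain 1000 src 1000 + 0 100 tgt 1000 + 500 600 1\n100\n\n"
    (ch,) = parse_chain(txt)
    assert len(ch.intervals) == 1 and not ch.gaps
    iv = ch.intervals[0]
    assert (iv.source_start, iv.source_end) == (0, 100)
    assert (iv.target_start, iv.target_end) == (500, 600)
    assert iv.offset == 500 and iv.strand == "+"


def test_parse_two_blocks_with_gap():
    txt = "chain 900 src 1000 + 10 112 tgt 1000 + 0 100 7\n60 2 0\n40\n\n"
    (ch,) = parse_chain(txt)
    assert [(i.source_start, i.source_end) for i in ch.intervals] == [(10, 70), (72, 112)]
    assert ch.gaps == [ChainGap(source_break=70, dsource=2, dtarget=0)]


def test_parse_minus_strand_converts_to_forward():
    # raw reverse coords [200,300) on a 1000 bp contig => forward [700,800)
    txt = "chain 800 src 1000 + 100 200 tgt 1000 - 200 300 3\n100\n\n"
    (ch,) = parse_chain(txt)
    iv = ch.intervals[0]
    assert (iv.target_start, iv.target_end) == (700, 800)
    # first source base pairs with last target base
    assert iv.lift(100) == 799 and iv.lift(199) == 700


@pytest.mark.parametrize("bad_text,exc", [
    ("chain 1 src 1000 + 0 100 tgt 1000 + 0 200 4\n100 0 100\n100\n\n",
     ChainValidationError),          # body exceeds header span
    ("chain 1 src 1000 + 0 100 tgt 1000 + 0 100\n", ChainParseError),
    ("100\n", ChainParseError),      # data line outside chain
    ("chain 1 src 1000 + 0 100 tgt 1000 + 0 100 1\nxyz\n", ChainParseError),
])
def test_parse_errors(bad_text, exc):
    with pytest.raises(exc):
        parse_chain(bad_text)


def test_contig_absent_from_lengths_map_is_error():
    txt = "chain 10 src 1000 + 0 100 tgt 1000 + 0 100 1\n100\n\n"
    with pytest.raises(ChainValidationError):
        parse_chain(txt, source_contig_lengths={"other": 1000})
    with pytest.raises(ChainValidationError):
        parse_chain(txt, source_contig_lengths={"src": 999})


def test_zero_zero_gap_merges_blocks():
    txt = "chain 10 src 1000 + 0 100 tgt 1000 + 0 100 1\n50 0 0\n50\n\n"
    (ch,) = parse_chain(txt)
    assert len(ch.intervals) == 1 and not ch.gaps


# ---------------------------------------------------------------------------
# rank bit vector
# ---------------------------------------------------------------------------


def test_rank_examples():
    bv = RankBitVector(10, [2, 3, 5])
    assert bv.rank(0) == 0
    assert bv.rank(5) == 2
    assert bv.rank(8) == 3
    assert bv.rank(10) == bv.count == 3
    with pytest.raises(ValueError):
        bv.rank(11)


def test_rank_matches_brute_force_scan():
    rng = np.random.default_rng(11)
    for _ in range(20):
        length = int(rng.integers(1, 3000))
        positions = rng.choice(length, size=min(length, int(rng.integers(0, 200))),
                               replace=False)
        bv = RankBitVector(length, positions)
        for p in rng.integers(0, length + 1, size=50):
            assert bv.rank(int(p)) == brute_rank(positions, int(p))


def test_rank_monotone_and_bounded():
    bv = RankBitVector(513, range(0, 513, 7))
    ranks = [bv.rank(p) for p in range(514)]
    assert ranks[0] == 0 and ranks[-1] == bv.count
    assert all(b - a in (0, 1) for a, b in zip(ranks, ranks[1:]))


# ---------------------------------------------------------------------------
# index construction and queries
# ---------------------------------------------------------------------------


def _simple_index():
    txt = (
        "chain 900 src 1000 + 100 200 tgt 2000 + 500 600 1\n100\n\n"
        "chain 800 src 1000 + 300 360 tgt 2000 + 700 760 2\n60\n\n"
        "chain 700 src 1000 + 400 480 tgt 2000 + 900 980 3\n80\n\n"
    )
    return ChainIndex(parse_chain(txt))


def test_disjoint_intervals_popcounts():
    idx = _simple_index()
    ci = idx._contigs["src"]
    assert ci.start_bv.count == ci.end_bv.count == 3 == idx.num_intervals("src")


def test_coverage_identity_exhaustive_small():
    pair = generate_genome_pair(20_000, seed=5)
    idx = ChainIndex(parse_chain(emit_chain(pair.cmap)))
    (contig,) = idx.source_contigs
    covered = np.zeros(idx.source_lengths[contig], dtype=bool)
    for s, e in idx.covered_spans(contig):
        covered[s:e] = True
    ci = idx._contigs[contig]
    for p in range(idx.source_lengths[contig]):
        diff = ci.start_bv.rank(p + 1) - ci.end_bv.rank(p + 1)
        assert diff in (0, 1)
        assert (diff == 1) == bool(covered[p])


def test_lift_position_identity_chain():
    txt = "chain 10 src 5000 + 0 5000 tgt 5000 + 0 5000 1\n5000\n\n"
    idx = ChainIndex(parse_chain(txt))
    lp = idx.lift_position("src", 1234)
    assert (lp.target_contig, lp.target_pos, lp.strand) == ("tgt", 1234, "+")


def test_lift_position_offset_and_minus_strand():
    txt = (
        "chain 90 src 1000 + 100 200 tgt 1000 + 500 600 1\n100\n\n"
        "chain 80 src 1000 + 300 400 tgt 1000 - 200 300 2\n100\n\n"
    )
    idx = ChainIndex(parse_chain(txt))
    assert idx.lift_position("src", 150).target_pos == 550
    assert idx.lift_position("src", 300).target_pos == 799
    assert idx.lift_position("src", 399).target_pos == 700
    assert not idx.lift_position("src", 250)
    assert not idx.lift_position("nope", 5)


def test_empty_chain_set_every_query_unliftable():
    idx = ChainIndex([], source_contig_lengths={"src": 100})
    ci = idx._contigs["src"]
    assert ci.start_bv.count == ci.end_bv.count == 0
    assert not idx.lift_position("src", 50)


def test_allowed_gap_snapping_and_left_tie():
    txt = (
        "chain 90 src 1000 + 100 200 tgt 1000 + 100 200 1\n100\n\n"
        "chain 80 src 1000 + 210 300 tgt 1000 + 300 390 2\n90\n\n"
    )
    idx = ChainIndex(parse_chain(txt), allowed_gap=6)
    # 203 is 4 from the left end (199) and 7 from the right start (210)
    lp = idx.lift_position("src", 203)
    assert lp.target_pos == 199 and lp.snap_distance == 4
    # 205: left distance 6, right distance 5 -> right neighbor
    assert idx.lift_position("src", 205).target_pos == 300
    # equidistant-ish tie at 204: left 5, right 6 -> left
    assert idx.lift_position("src", 204).target_pos == 199
    # beyond threshold on a no-snap index
    assert not ChainIndex(parse_chain(txt)).lift_position("src", 203)


def test_overlap_resolution_prefers_higher_score():
    txt = (
        "chain 1000 src 1000 + 0 100 tgt 1000 + 0 100 1\n100\n\n"
        "chain 10 src 1000 + 50 150 tgt 1000 + 500 600 2\n100\n\n"
    )
    idx = ChainIndex(parse_chain(txt))
    assert idx.lift_position("src", 75).target_pos == 75      # high-score chain
    assert idx.lift_position("src", 120).target_pos == 570    # trimmed remainder
    assert idx.n_dropped_overlap == 1


def test_duplicate_intervals_deduplicated():
    txt = (
        "chain 100 src 1000 + 0 100 tgt 1000 + 0 100 1\n100\n\n"
        "chain 100 src 1000 + 0 100 tgt 1000 + 0 100 2\n100\n\n"
    )
    idx = ChainIndex(parse_chain(txt))
    assert idx.num_intervals("src") == 1
    assert idx.n_deduplicated == 1


# ---------------------------------------------------------------------------
# oracle equivalence, inversion, serialization
# ---------------------------------------------------------------------------


def test_lift_position_agrees_with_linear_scan(chain_index, genome_pair):
    rng = np.random.default_rng(17)
    pieces = [iv for ch in chain_index.chains.values() for iv in ch.intervals]
    L = genome_pair.cmap.source_length
    for p in rng.integers(0, L, size=3000):
        expect = linear_scan_lift(pieces, "src", int(p))
        got = chain_index.lift_position("src", int(p))
        got = (got.target_contig, got.target_pos, got.strand) if got else None
        assert got == expect


def test_invert_roundtrip_interior_positions(chain_index, genome_pair):
    inv = chain_index.invert()
    rng = np.random.default_rng(23)
    n_checked = 0
    for p in rng.integers(0, genome_pair.cmap.source_length, size=4000):
        lp = chain_index.lift_position("src", int(p))
        if not lp:
            continue
        back = inv.lift_position(lp.target_contig, lp.target_pos)
        assert back and back.target_pos == int(p) and back.target_contig == "src"
        n_checked += 1
    assert n_checked > 1000


def test_invert_identity_chain_is_self_inverse():
    txt = "chain 10 src 500 + 0 500 tgt 500 + 0 500 1\n500\n\n"
    idx = ChainIndex(parse_chain(txt))
    inv = idx.invert()
    for p in (0, 17, 499):
        assert inv.lift_position("tgt", p).target_pos == p


def test_gap_bases_unliftable_both_directions():
    txt = "chain 10 src 1000 + 0 100 tgt 1000 + 0 110 1\n40 10 20\n50\n\n"
    idx = ChainIndex(parse_chain(txt))
    inv = idx.invert()
    assert not idx.lift_position("src", 45)    # inside dsource gap
    assert not inv.lift_position("tgt", 50)    # inside dtarget gap


def test_serialization_roundtrip_full_query_sweep(tmp_path, chain_index):
    path = str(tmp_path / "idx.clft")
    chain_index.save(path)
    from liftkit.chain import ChainIndex as CI
    idx2 = CI.load(path)
    (contig,) = chain_index.source_contigs
    for p in range(0, chain_index.source_lengths[contig], 97):
        a = chain_index.lift_position(contig, p)
        b = idx2.lift_position(contig, p)
        assert bool(a) == bool(b)
        if a:
            assert (a.target_contig, a.target_pos, a.strand) == (
                b.target_contig, b.target_pos, b.strand)


def test_constant_time_rank_contract():
    """Per-query cost must not grow with interval count (rank directory)."""
    import time
    times = {}
    for m in (100, 100_00):
        txt_chains = []
        # m disjoint 5bp intervals
        step = 10
        length = m * step + 10
        chains = []
        for i in range(m):
            s = i * step
            chains.append(Chain(
                chain_id=i, score=1, source_contig="src", source_size=length,
                source_start=s, source_end=s + 5, target_contig="tgt",
                target_size=length, strand="+", target_start=s, target_end=s + 5,
                intervals=[], gaps=[]))
        from liftkit.chain import ChainInterval
        for c in chains:
            c.intervals = [ChainInterval("src", c.source_start, c.source_end,
                                         "tgt", c.target_start, c.target_end,
                                         "+", c.chain_id)]
        idx = ChainIndex(chains)
        qs = np.random.default_rng(1).integers(0, length, size=4000)
        t0 = time.perf_counter()
        for p in qs:
            idx.lift_position("src", int(p))
        times[m] = (time.perf_counter() - t0) / len(qs)
    assert times[100_00] < 2.0 * times[100]
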