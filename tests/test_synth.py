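"""Synthetic genome pairs, chain emission, read simulation, evaluation."""

import math

import numpy as np
import pytest

from liftkit.chain import ChainIndex, parse_chain
from liftkit.engine import reverse_complement
from liftkit.synth import (
    Deletion,
    Insertion,
    Inversion,
    NovelSegment,
    Snv,
    SourceDuplication,
    TargetDuplication,
    aggregate_f1,
    apply_edits,
    emit_chain,
    evaluate_correctness,
    generate_genome_pair,
    oracle_lift,
    random_genome,
    simulate_reads,
    write_fasta,
    read_fasta,
    write_fastq,
    write_truth,
    load_truth,
)


def test_zero_edits_identical_genomes_identity_map():
    base = random_genome(500, seed=1)["chr1"]
    pair = apply_edits(base, [])
    assert pair.source["src"] == pair.target["tgt"] == base
    assert len(pair.cmap.blocks) == 1
    assert pair.cmap.lift(123) == ("tgt", 123, "+")


def test_single_insertion_creates_one_dsource_gap():
    base = random_genome(300, seed=2)["chr1"]
    pair = apply_edits(base, [Insertion(100, "AC")])
    assert len(pair.source["src"]) == 302
    assert pair.cmap.lift(99) == ("tgt", 99, "+")
    assert pair.cmap.lift(100) is None and pair.cmap.lift(101) is None
    assert pair.cmap.lift(102) == ("tgt", 100, "+")
    chains = parse_chain(emit_chain(pair.cmap))
    assert len(chains) == 1
    (gap,) = chains[0].gaps
    assert (gap.dsource, gap.dtarget) == (2, 0)


def test_edit_classes_shape_the_two_genomes():
    base = random_genome(4000, seed=3)["chr1"]
    edits = [Snv(100), Deletion(500, 10), Inversion(1000, 300),
             SourceDuplication(2000, 400, divergence=0.0),
             TargetDuplication(3000, 200), NovelSegment(3600, "ACGT" * 50)]
    pair = apply_edits(base, edits, seed=0)
    src, tgt = pair.source["src"], pair.target["tgt"]
    assert len(tgt) == len(base) + 200          # target duplication only
    assert len(src) == len(base) + 400 + 200 - 10  # dup + novel - deletion
    assert src[100] != tgt[100]                 # SNV
    assert tgt[500:510] == base[500:510]        # deleted from source only
    # inversion: source carries the reverse complement
    inv_block = [b for b in pair.cmap.blocks if b.strand == "-"]
    assert len(inv_block) == 1
    b = inv_block[0]
    assert src[b.source_start:b.source_end] == reverse_complement(
        tgt[b.target_start:b.target_end])
    # source duplication: two adjacent identical copies in source
    assert src.count(base[2000:2400]) == 2


def test_generate_deterministic_and_seed_sensitive():
    a = generate_genome_pair(10_000, seed=4)
    b = generate_genome_pair(10_000, seed=4)
    c = generate_genome_pair(10_000, seed=5)
    assert a.source == b.source and a.target == b.target
    assert a.cmap.blocks == b.cmap.blocks
    assert c.source != a.source


def test_chain_roundtrip_on_random_edit_scripts():
    for seed in range(25):
        pair = generate_genome_pair(8_000, seed=seed, edit_rates={
            "snv": 2e-3, "ins": 3e-4, "del": 3e-4, "inv": 1e-4,
            "source_dup": 5e-5, "target_dup": 5e-5, "novel": 0.0})
        chains = parse_chain(emit_chain(pair.cmap))
        rebuilt = sorted(
            (iv.source_start, iv.source_end, iv.target_start, iv.target_end,
             iv.strand)
            for ch in chains for iv in ch.intervals)
        original = sorted(
            (b.source_start, b.source_end, b.target_start, b.target_end,
             b.strand)
            for b in pair.cmap.blocks)
        assert rebuilt == original


def test_oracle_lift_identity_and_gap():
    base = random_genome(200, seed=6)["chr1"]
    pair = apply_edits(base, [Insertion(50, "AAAA")])
    assert oracle_lift(pair.cmap, "src", 10) == ("tgt", 10, "+")
    assert oracle_lift(pair.cmap, "src", 52) is None
    assert oracle_lift(pair.cmap, "other", 10) is None


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def test_simulated_reads_match_origin_without_errors():
    g = random_genome(5_000, seed=7)
    pairs, truth = simulate_reads(g, 50, read_len=80, err_rate=0.0, seed=8)
    for p in pairs:
        for seq, t in ((p.seq1, p.truth1), (p.seq2, p.truth2)):
            origin = g[t.contig][t.pos:t.pos + 80]
            assert seq == (origin if t.strand == "+" else reverse_complement(origin))


def test_simulation_deterministic_given_seed(tmp_path):
    g = random_genome(5_000, seed=7)
    p1, t1 = simulate_reads(g, 100, seed=9)
    p2, t2 = simulate_reads(g, 100, seed=9)
    assert [(x.seq1, x.seq2) for x in p1] == [(x.seq1, x.seq2) for x in p2]
    assert t1 == t2
    f1a, f2a = tmp_path / "a1.fq", tmp_path / "a2.fq"
    f1b, f2b = tmp_path / "b1.fq", tmp_path / "b2.fq"
    write_fastq(p1, str(f1a), str(f2a))
    write_fastq(p2, str(f1b), str(f2b))
    assert f1a.read_bytes() == f1b.read_bytes()
    assert f2a.read_bytes() == f2b.read_bytes()
    p3, _ = simulate_reads(g, 100, seed=10)
    assert [(x.seq1, x.seq2) for x in p3] != [(x.seq1, x.seq2) for x in p1]


def test_error_rate_within_binomial_bounds():
    g = random_genome(20_000, seed=11)
    err = 0.01
    pairs, truth = simulate_reads(g, 500, read_len=100, err_rate=err, seed=12)
    n_bases = 0
    n_mism = 0
    for p in pairs:
        for seq, t in ((p.seq1, p.truth1), (p.seq2, p.truth2)):
            origin = g[t.contig][t.pos:t.pos + 100]
            if t.strand == "-":
                origin = reverse_complement(origin)
            n_bases += 100
            n_mism += sum(a != b for a, b in zip(seq, origin))
    # substituting to a random different base always mismatches
    sigma = math.sqrt(n_bases * err * (1 - err))
    assert abs(n_mism - n_bases * err) < 3 * sigma


def test_truth_table_tsv_roundtrip(tmp_path):
    g = random_genome(5_000, seed=13)
    _, truth = simulate_reads(g, 20, seed=14)
    path = tmp_path / "truth.tsv"
    write_truth(truth, str(path))
    assert load_truth(str(path)) == truth


def test_fasta_roundtrip(tmp_path):
    g = {"a": random_genome(333, seed=15)["chr1"], "b": "ACGT" * 10}
    path = tmp_path / "g.fa"
    write_fasta(g, str(path))
    assert read_fasta(str(path)) == g


def test_diploid_sampling_records_haplotype():
    g0 = random_genome(5_000, seed=16)
    g1 = {"chr1": reverse_complement(g0["chr1"])}
    pairs, truth = simulate_reads([g0, g1], 200, seed=17)
    haps = {t.haplotype for t in truth.values()}
    assert haps == {0, 1}


# ---------------------------------------------------------------------------
# evaluation semantics
# ---------------------------------------------------------------------------


def _truth_one():
    from liftkit.synth import TruthEntry
    return {("r", 1): TruthEntry("c", 1000, "+")}


@pytest.mark.parametrize("contig,pos,expected", [
    ("c", 1005, 1),   # within tolerance
    ("c", 1010, 1),   # |delta| == 10 is correct
    ("c", 1011, 0),   # |delta| == 11 is incorrect
    ("c", 990, 1),
    ("c", 989, 0),
    ("d", 1000, 0),   # cross-contig
    (None, None, 0),  # unmapped
])
def test_ten_bp_rule(contig, pos, expected):
    res = evaluate_correctness([("r", 1, contig, pos)], _truth_one(), tol=10)
    assert res["n_correct"] == expected and res["n_total"] == 1


def test_read_absent_from_truth_is_error():
    with pytest.raises(KeyError):
        evaluate_correctness([("ghost", 1, "c", 5)], _truth_one())


def test_all_unmapped_fraction_zero():
    res = evaluate_correctness([], _truth_one())
    assert res["fraction"] == 0.0


def test_f1_formula_and_additivity():
    assert aggregate_f1(9, 1, 1) == pytest.approx(0.9)
    assert aggregate_f1(0, 5, 5) == 0.0
    assert aggregate_f1(45, 5, 5) == pytest.approx(0.9)
    # summing dataset counts first equals aggregating
    assert aggregate_f1(40 + 5, 4 + 1, 4 + 1) == pytest.approx(0.9)
    assert math.isnan(aggregate_f1(0, 0, 0))
    with pytest.raises(ValueError):
        aggregate_f1(-1, 0, 0)
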