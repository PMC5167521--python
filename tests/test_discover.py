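import numpy as np
import pytest

from tevar import discover, io, sim
from tevar.config import DiscoverParams
from tevar.discover import (
    DiscordantPair,
    Evidence,
    LibraryStats,
    Mate,
    SplitRead,
    insertion_read_threshold,
)

STATS = LibraryStats(insert_mean=400, insert_sd=50, mean_coverage=20, read_length=100)


@pytest.mark.parametrize(
    "coverage,expected",
    [(50, 5), (8, 2), (10, 2), (10.5, 2), (11, 2), (35, 3), (200, 20)],
)
def test_insertion_read_threshold(coverage, expected):
    assert insertion_read_threshold(coverage) == expected


def test_threshold_strict_doubles():
    assert insertion_read_threshold(50, DiscoverParams(strict=True)) == 10


def test_threshold_rejects_nonpositive_coverage():
    with pytest.raises(ValueError):
        insertion_read_threshold(0)


def test_library_stats_match_generator_moments(small_sim, small_discover):
    """Estimates recovered from the SAM agree with the trimmed sample
    moments of the generator's own insert draws to within 2 bp."""
    stats = small_discover.stats
    mean, sd = discover.trimmed_moments(small_sim["reads"].insert)
    assert abs(stats.insert_mean - mean) < 2.0
    assert abs(stats.insert_sd - sd) < 2.0
    assert stats.read_length == 100
    assert stats.mean_coverage == pytest.approx(20, rel=0.05)


def test_library_stats_constant_inserts(tmp_path):
    genome = {"chr1": sim._random_sequence(np.random.default_rng(0), 200_000)}
    profile = sim.ReadProfile(coverage=5, insert_mean=500, insert_sd=0, seed=1)
    reads = sim.generate_reads(genome, profile)
    sam = tmp_path / "const.sam"
    sim.emit_ideal_alignments(reads, None, genome, sam)
    layout = io.layout_from_genome(genome)
    stats = discover.estimate_library_stats(sam, layout)
    assert stats.insert_mean == pytest.approx(500)
    assert stats.insert_sd == pytest.approx(0)


def test_library_stats_requires_proper_pairs(small_sim):
    params = DiscoverParams(min_proper_pairs=10**9)
    with pytest.raises(discover.DiscoverError, match="proper pairs"):
        discover.estimate_library_stats(small_sim["sam"], small_sim["layout"], params)


# ---------------------------------------------------------------------------
# Evidence extraction on a hand-built SAM
# ---------------------------------------------------------------------------


def _sam(tmp_path, records):
    path = tmp_path / "hand.sam"
    header = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:100000\n@SQ\tSN:chr2\tLN:100000\n"
    path.write_text(header + "".join(r + "\n" for r in records))
    return str(path)


def _pair(name, chrom1, pos1, chrom2, pos2, tlen, proper=False):
    flag1 = 1 | 64 | 32 | (2 if proper else 0)
    flag2 = 1 | 128 | 16 | (2 if proper else 0)
    rn2 = "=" if chrom1 == chrom2 else chrom2
    rn1 = "=" if chrom1 == chrom2 else chrom1
    seq = "A" * 100
    q = "I" * 100
    return [
        f"{name}\t{flag1}\t{chrom1}\t{pos1 + 1}\t60\t100M\t{rn2}\t{pos2 + 1}\t{tlen}\t{seq}\t{q}",
        f"{name}\t{flag2}\t{chrom2}\t{pos2 + 1}\t60\t100M\t{rn1}\t{pos1 + 1}\t{-tlen}\t{seq}\t{q}",
    ]


def _split(name, pos1, pos2, mapq=60):
    seq = "A" * 100
    q = "I" * 100
    sa = f"SA:Z:chr1,{pos2 + 1},+,50S50M,{mapq},0;"
    sa_back = f"SA:Z:chr1,{pos1 + 1},+,50M50S,{mapq},0;"
    return [
        f"{name}\t65\tchr1\t{pos1 + 1}\t{mapq}\t50M50S\t=\t{pos1 + 1}\t0\t{seq}\t{q}\t{sa}",
        f"{name}\t2113\tchr1\t{pos2 + 1}\t{mapq}\t50S50M\t=\t{pos1 + 1}\t0\t{seq}\t{q}\t{sa_back}",
    ]


def _layout():
    return io.GenomeLayout({"chr1": 100_000, "chr2": 100_000})


def test_discordance_boundary(tmp_path):
    """mean 400, sd 50: reference span 700 is discordant, 500 is not."""
    records = []
    records += _pair("far", "chr1", 1000, "chr1", 1600, 700)    # span 700
    records += _pair("near", "chr1", 5000, "chr1", 5400, 500, proper=True)
    sam = _sam(tmp_path, sorted(records, key=lambda r: int(r.split("\t")[3])))
    ev = discover.extract_evidence(sam, STATS, _layout())
    assert [p.name for p in ev.discordant] == ["far"]


def test_interchromosomal_pair_is_discordant(tmp_path):
    records = _pair("xc", "chr1", 1000, "chr2", 2000, 0)
    sam = _sam(tmp_path, records)
    ev = discover.extract_evidence(sam, STATS, _layout())
    assert len(ev.discordant) == 1
    assert ev.discordant[0].a.chrom != ev.discordant[0].b.chrom


def test_split_distance_and_mapq_filters(tmp_path):
    records = []
    records += _split("close", 1000, 3000)          # 2 kb apart -> dropped
    records += _split("far", 10_000, 20_000)        # 10 kb -> kept
    records += _split("lowq", 30_000, 40_000, mapq=3)  # MAPQ < 5 -> dropped
    sam = _sam(tmp_path, sorted(records, key=lambda r: int(r.split("\t")[3])))
    ev = discover.extract_evidence(sam, STATS, _layout())
    assert [s.name.split("/")[0] for s in ev.splits] == ["far"]
    split = ev.splits[0]
    assert split.junction1 == 10_050   # trailing clip: junction at segment end
    assert split.junction2 == 20_000   # leading clip: junction at segment start


def test_depth_accumulates_aligned_bases(tmp_path):
    records = _pair("p", "chr1", 1000, "chr1", 1300, 400, proper=True)
    sam = _sam(tmp_path, records)
    ev = discover.extract_evidence(sam, STATS, _layout())
    depth = ev.depth["chr1"]
    assert depth[1050] == 1 and depth[1350] == 1
    assert depth[1200] == 0 and depth[500] == 0


# ---------------------------------------------------------------------------
# Insertion calling rules on synthetic evidence
# ---------------------------------------------------------------------------

ANN = [io.TEAnnotation("chr1", 50_000, 52_000, "TE1", "FAM1", "SF1")]


def _disc(name, anchor_start, anchor_strand, te_start=50_200):
    anchor = Mate("chr1", anchor_start, anchor_start + 100, anchor_strand)
    te_mate = Mate("chr1", te_start, te_start + 100, "+")
    a, b = sorted([anchor, te_mate], key=lambda m: (m.chrom, m.start))
    return DiscordantPair(name, a, b)


def _split_anchor(name, anchor_start, junction, te_start=50_300):
    seg1 = Mate("chr1", anchor_start, anchor_start + 60, "+")
    seg2 = Mate("chr1", te_start, te_start + 40, "+")
    return SplitRead(name, seg1, seg2, 60, junction, te_start)


def _empty_depth():
    return {"chr1": np.full(100_000, 20, dtype=np.int32)}


def test_no_evidence_no_calls():
    ev = Evidence([], [], _empty_depth())
    assert discover.call_insertions(ev, ANN, STATS) == []


def test_facing_pairs_call_at_threshold():
    """Two facing discordant pairs linked to one TE reach the coverage-20
    threshold of 2; the same support one-sided needs 4 reads."""
    facing = Evidence(
        [_disc("f", 9_800, "+"), _disc("r", 10_050, "-")], [], _empty_depth()
    )
    calls = discover.call_insertions(facing, ANN, STATS)
    assert len(calls) == 1
    call = calls[0]
    assert call.has_facing_pairs
    assert call.te_ids == ("TE1",) and call.families == ("FAM1",)
    assert 9_800 <= call.start <= call.end <= 10_150

    one_sided = Evidence(
        [_disc("f1", 9_800, "+"), _disc("f2", 9_850, "+")], [], _empty_depth()
    )
    assert discover.call_insertions(one_sided, ANN, STATS) == []


def test_one_sided_support_doubles_requirement():
    pairs = [_disc(f"f{i}", 9_800 + i * 10, "+") for i in range(4)]
    calls = discover.call_insertions(Evidence(pairs, [], _empty_depth()), ANN, STATS)
    assert len(calls) == 1
    assert not calls[0].has_facing_pairs


def test_split_read_narrows_breakpoint():
    ev = Evidence(
        [_disc("f", 9_800, "+"), _disc("r", 10_050, "-")],
        [_split_anchor("s", 9_950, junction=10_000)],
        _empty_depth(),
    )
    (call,) = discover.call_insertions(ev, ANN, STATS)
    assert call.start == call.end == 10_000
    assert call.n_split == 1 and call.n_discordant == 2


def test_breakpoint_interval_capped(small_discover):
    cap = small_discover.stats.insert_mean + 4 * small_discover.stats.insert_sd
    for call in small_discover.insertions:
        assert call.end - call.start <= cap


def test_calls_meet_support_invariant(small_discover):
    thr = insertion_read_threshold(small_discover.stats.mean_coverage)
    for call in small_discover.insertions:
        required = thr if call.has_facing_pairs else 2 * thr
        assert call.n_split + call.n_discordant >= required


# ---------------------------------------------------------------------------
# Absence calling rules on synthetic evidence
# ---------------------------------------------------------------------------


def _span_pair(name, left_end, right_start):
    a = Mate("chr1", left_end - 100, left_end, "+")
    b = Mate("chr1", right_start, right_start + 100, "-")
    return DiscordantPair(name, a, b)


def _depth_with_hole(hole_start, hole_end, base=20):
    depth = np.full(100_000, base, dtype=np.int32)
    depth[hole_start:hole_end] = 0
    return {"chr1": depth}


def test_absence_called_on_spanned_zero_coverage_te():
    te = io.TEAnnotation("chr1", 40_000, 41_000, "TEdel", "FAM1", "SF1")
    pairs = [_span_pair(f"p{i}", 39_900 - i, 41_100 + i) for i in range(5)]
    ev = Evidence(pairs, [], _depth_with_hole(40_000, 41_000))
    calls = discover.call_absences(ev, [te], STATS, _layout())
    assert len(calls) == 1
    call = calls[0]
    assert call.te_ids == ("TEdel",)
    assert call.n_spanning == 5
    assert call.internal_coverage == 0.0
    assert call.flanking_coverage == pytest.approx(20)


def test_partial_span_below_80pct_not_called():
    te = io.TEAnnotation("chr1", 40_000, 41_000, "TEdel", "FAM1", "SF1")
    # gap covers only 70% of the TE
    pairs = [_span_pair(f"p{i}", 40_300, 41_100) for i in range(5)]
    ev = Evidence(pairs, [], _depth_with_hole(40_300, 41_000))
    assert discover.call_absences(ev, [te], STATS, _layout()) == []


def test_intermediate_depth_ratio_needs_double_support():
    te = io.TEAnnotation("chr1", 40_000, 41_000, "TEdel", "FAM1", "SF1")
    depth = np.full(100_000, 20, dtype=np.int32)
    depth[40_000:41_000] = 10              # ratio 0.5: < 1 but not < 0.1
    pairs2 = [_span_pair(f"p{i}", 39_900, 41_100) for i in range(2)]
    pairs4 = [_span_pair(f"p{i}", 39_900, 41_100) for i in range(4)]
    assert discover.call_absences(
        Evidence(pairs2, [], {"chr1": depth}), [te], STATS, _layout()
    ) == []
    calls = discover.call_absences(
        Evidence(pairs4, [], {"chr1": depth}), [te], STATS, _layout()
    )
    assert len(calls) == 1


def test_wide_spans_discarded():
    te = io.TEAnnotation("chr1", 40_000, 41_000, "TEdel", "FAM1", "SF1")
    pairs = [_span_pair(f"p{i}", 30_000, 55_000) for i in range(5)]  # 25 kb
    ev = Evidence(pairs, [], _depth_with_hole(40_000, 41_000))
    assert discover.call_absences(ev, [te], STATS, _layout()) == []


# ---------------------------------------------------------------------------
# End-to-end on the simulated sample
# ---------------------------------------------------------------------------


def test_round_trip_recovers_planted_variants(small_sim, small_discover):
    res = sim.evaluate_calls(
        small_discover.records, small_sim["truth"], 100,
        annotation=small_sim["annotation"],
    )
    assert res.insertion.sensitivity == 1.0
    assert res.insertion.fdr == 0.0
    assert res.absence.sensitivity == 1.0
    assert res.absence.fdr == 0.0


@pytest.mark.parametrize("seed", [101, 202])
def test_round_trip_other_seeds(tmp_path, seed):
    genome, ann = sim.simulate_genome(
        n_chrom=2, chrom_length=400_000, n_tes=40, seed=seed
    )
    derived, truth = sim.apply_variants(genome, ann, 4, 4, 6, seed=seed + 1)
    reads = sim.generate_reads(derived, sim.ReadProfile(coverage=20, seed=seed + 2))
    sam = tmp_path / "rt.sam"
    sim.emit_ideal_alignments(reads, truth.blocks, genome, sam)
    layout = io.layout_from_genome(genome)
    result = discover.discover_sample(str(sam), ann, layout)
    res = sim.evaluate_calls(result.records, truth, 100, annotation=ann)
    assert res.insertion.sensitivity >= 0.95 and res.insertion.fdr <= 0.05
    assert res.absence.sensitivity >= 0.95 and res.absence.fdr <= 0.05


def test_recategorize_round_trip(small_discover):
    records = discover.recategorize_by_reference(
        small_discover.insertions, small_discover.absences, accession="s1"
    )
    assert len(records) == len(small_discover.insertions) + len(
        small_discover.absences
    )
    pres = [r for r in records if r.variant_type == "presence"]
    abse = [r for r in records if r.variant_type == "absence"]
    assert len(pres) == len(small_discover.insertions)
    for rec, call in zip(abse, small_discover.absences):
        assert rec.te_ids == call.te_ids      # absence keeps its te_id
    assert discover.recategorize_by_reference([], []) == []
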