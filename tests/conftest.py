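import numpy as np
import pytest

from tevar import discover, io, refine, sim


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A 2 x 400 kb genome with 40 TEs, 5 copy-paste + 5 cut-paste
    insertions and 8 deletions, sequenced at 20x through the
    ideal-alignment path."""
    genome, ann = sim.simulate_genome(
        n_chrom=2, chrom_length=400_000, n_tes=40, seed=7
    )
    derived, truth = sim.apply_variants(genome, ann, 5, 5, 8, seed=8)
    profile = sim.ReadProfile(coverage=20, seed=9)
    reads = sim.generate_reads(derived, profile)
    sam = tmp_path_factory.mktemp("sim") / "ideal.sam"
    sim.emit_ideal_alignments(reads, truth.blocks, genome, sam)
    return {
        "genome": genome,
        "annotation": ann,
        "derived": derived,
        "truth": truth,
        "reads": reads,
        "profile": profile,
        "sam": str(sam),
        "layout": io.layout_from_genome(genome),
    }


@pytest.fixture(scope="session")
def small_discover(small_sim):
    return discover.discover_sample(
        small_sim["sam"], small_sim["annotation"], small_sim["layout"], accession="s1"
    )


@pytest.fixture(scope="session")
def refine_scenario(tmp_path_factory):
    """Five 12x samples sharing all planted insertions, plus one 4x
    sample with the reads over one site removed; merged sites are built
    from the high-coverage samples only, so the 4x sample is a
    non-carrier everywhere."""
    genome, ann = sim.simulate_genome(
        n_chrom=2, chrom_length=500_000, n_tes=40, seed=21
    )
    derived, truth = sim.apply_variants(genome, ann, 8, 6, 4, seed=22)
    layout = io.layout_from_genome(genome)
    workdir = tmp_path_factory.mktemp("refine")

    results = {}
    for i in range(5):
        profile = sim.ReadProfile(coverage=12, seed=300 + i)
        reads = sim.generate_reads(derived, profile)
        sam = workdir / f"hi{i}.sam"
        sim.emit_ideal_alignments(reads, truth.blocks, genome, sam)
        results[f"hi{i}"] = discover.discover_sample(
            str(sam), ann, layout, accession=f"hi{i}"
        )
    sites = refine.merge_insertions({k: r.insertions for k, r in results.items()})

    masked_ins = truth.insertions[0]
    dchrom, dstart, dend = sim.derived_interval_of_insertion(truth, masked_ins)
    profile = sim.ReadProfile(coverage=4, seed=310)
    low_reads = sim.generate_reads(derived, profile)
    rl = profile.read_length
    low_reads = sim.drop_pairs_overlapping(
        low_reads, dchrom, dstart - 3 * rl, dend + 3 * rl
    )
    low_sam = workdir / "low.sam"
    sim.emit_ideal_alignments(low_reads, truth.blocks, genome, low_sam)
    low_result = discover.discover_sample(str(low_sam), ann, layout, accession="low")
    low_evidence = discover.extract_evidence(str(low_sam), low_result.stats, layout)

    masked_sites = [
        s.site_id
        for s in sites
        if s.chrom == masked_ins.chrom
        and abs(s.start - masked_ins.position) <= 200
    ]
    return {
        "annotation": ann,
        "layout": layout,
        "truth": truth,
        "sites": sites,
        "high_results": results,
        "low_result": low_result,
        "low_evidence": low_evidence,
        "masked_site_ids": masked_sites,
    }
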