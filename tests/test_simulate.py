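"""Synthetic genomes, variant implantation and capture simulation."""

import numpy as np
import pytest

from osseq.design import finalize_catalog, make_candidate
from osseq.genome import Genome, reverse_complement
from osseq.kmer import MapabilityCode, classify_positions
from osseq.qc import read_sam
from osseq.simulate import (
    Deletion, Insertion, Inversion, SimConfig, Snv, SourceGenome,
    implant_variants, simulate_capture, simulate_genome,
)


def test_same_seed_same_genome():
    g1, _ = simulate_genome(500, 99)
    g2, _ = simulate_genome(500, 99)
    assert g1["chr1"].seq == g2["chr1"].seq
    g3, _ = simulate_genome(500, 100)
    assert g1["chr1"].seq != g3["chr1"].seq


def test_repeat_fraction_zero_means_no_annotations():
    _, repeats = simulate_genome(500, 1, repeat_fraction=0.0)
    assert repeats == []


def test_embedded_repeat_tract_is_classified_repetitive():
    genome, repeats = simulate_genome(
        3000, 5, repeat_fraction=0.08, repeat_unit="AT", repeat_tract_len=400
    )
    assert repeats
    track = classify_positions(genome, 20, 1)
    chrom, s, e = repeats[0]
    arr = track.track(chrom)
    inner = arr[s + 5 : e - 25]
    assert (inner == MapabilityCode.REPETITIVE).all()


class TestImplantVariants:
    def test_snv_changes_one_base(self):
        genome, _ = simulate_genome(200, 1)
        seq = genome["chr1"].seq
        alt = "A" if seq[50] != "A" else "C"
        derived = implant_variants(genome, [Snv("chr1", 50, alt)])
        dseq = derived.genome["chr1"].seq
        assert dseq[50] == alt
        assert sum(a != b for a, b in zip(seq, dseq)) == 1

    def test_deletion_shrinks_and_records_junction(self):
        genome, _ = simulate_genome(20_000, 2)
        derived = implant_variants(genome, [Deletion("chr1", 2000, 12_000)])
        assert len(derived.genome["chr1"].seq) == 10_000
        (j,) = derived.junctions
        assert (j.pos1, j.pos2, j.sv_type) == (2000, 12_000, "DEL")
        # lift: positions after the deletion map back with the offset
        assert derived.lift["chr1"].ref_to_derived(12_500) == 2500
        assert derived.lift["chr1"].contiguous_ref_interval(1990, 2010) is None

    def test_inversion_reverse_complements_segment(self):
        genome, _ = simulate_genome(1000, 3)
        seq = genome["chr1"].seq
        derived = implant_variants(genome, [Inversion("chr1", 300, 600)])
        dseq = derived.genome["chr1"].seq
        assert dseq[300:600] == reverse_complement(seq[300:600])
        assert dseq[:300] == seq[:300] and dseq[600:] == seq[600:]
        lifted = derived.lift["chr1"].contiguous_ref_interval(310, 330)
        assert lifted == (570, 590, "-")

    def test_insertion_and_overlap_rejection(self):
        genome, _ = simulate_genome(500, 4)
        derived = implant_variants(genome, [Insertion("chr1", 100, "ACGTACGT")])
        assert len(derived.genome["chr1"].seq) == 508
        with pytest.raises(ValueError):
            implant_variants(
                genome,
                [Deletion("chr1", 100, 200), Inversion("chr1", 150, 300)],
            )


@pytest.fixture(scope="module")
def probe_setup():
    genome, _ = simulate_genome(6000, 11)
    probes = finalize_catalog(
        [
            make_candidate(genome, "chr1", 2000, "+", "a"),
            make_candidate(genome, "chr1", 3500, "-", "b"),
        ]
    )
    return genome, probes


def test_full_efficiency_captures_all_eligible(probe_setup):
    genome, probes = probe_setup
    config = SimConfig(
        n_fragments=2000, capture_efficiency=1.0, efficiency_sigma=0.0,
        error_rate=0.0,
    )
    sim = simulate_capture(
        [SourceGenome("ref", genome, 1.0)], probes, config, 5
    )
    assert sim.reads
    by_probe = {p.probe_id: p for p in probes}
    for r in sim.reads:
        assert r.read2[:40] == by_probe[r.probe_id].target_seq_40
        assert r.fully_aligned
        # Read 1 starts at the first genomic base past the probe footprint
        probe = by_probe[r.probe_id]
        if probe.strand == "+":
            assert r.ref_pos == probe.anchor_end and r.ref_strand == "+"
        else:
            assert r.ref_pos + len(r.read1) == probe.anchor_start
            assert r.ref_strand == "-"
        assert r.read1 not in ("",)


def test_capture_count_tracks_efficiency(probe_setup):
    genome, probes = probe_setup
    # expected captures per probe = n_eligible * efficiency; check 3-sigma
    n = 30_000
    config_full = SimConfig(
        n_fragments=n, capture_efficiency=1.0, efficiency_sigma=0.0, error_rate=0.0
    )
    eligible = len(
        simulate_capture([SourceGenome("ref", genome, 1.0)], [probes[0]], config_full, 7).reads
    )
    config = SimConfig(
        n_fragments=n, capture_efficiency=0.049, efficiency_sigma=0.0, error_rate=0.0
    )
    captured = len(
        simulate_capture([SourceGenome("ref", genome, 1.0)], [probes[0]], config, 7).reads
    )
    p = 0.049
    sigma = np.sqrt(eligible * p * (1 - p))
    assert abs(captured - eligible * p) < 3 * sigma


def test_mixture_weights_shape_read_provenance(probe_setup):
    genome, probes = probe_setup
    config = SimConfig(n_fragments=40_000, efficiency_sigma=0.0, error_rate=0.0)
    sim = simulate_capture(
        [SourceGenome("a", genome, 0.8), SourceGenome("b", genome, 0.2)],
        probes, config, 13,
    )
    frac_b = np.mean([r.source == "b" for r in sim.reads])
    sigma = np.sqrt(0.2 * 0.8 / len(sim.reads))
    assert abs(frac_b - 0.2) < 4 * sigma


def test_determinism_and_conservation(probe_setup, tmp_path):
    genome, probes = probe_setup
    config = SimConfig(n_fragments=5000)
    sims = [
        simulate_capture([SourceGenome("ref", genome, 1.0)], probes, config, 17)
        for _ in range(2)
    ]
    f1a, f1b = tmp_path / "a1.fq", tmp_path / "b1.fq"
    f2a, f2b = tmp_path / "a2.fq", tmp_path / "b2.fq"
    sims[0].write_fastq(f1a, f2a)
    sims[1].write_fastq(f1b, f2b)
    assert f1a.read_bytes() == f1b.read_bytes()
    assert f2a.read_bytes() == f2b.read_bytes()
    # conservation: FASTQ records == truth rows == provenance entries
    n_fastq = f1a.read_text().count("\n") // 4
    assert n_fastq == len(sims[0].reads) == len(sims[0].truth_frame())


def test_truth_sam_round_trips_through_pysam(probe_setup, tmp_path):
    genome, probes = probe_setup
    config = SimConfig(n_fragments=3000)
    sim = simulate_capture([SourceGenome("ref", genome, 1.0)], probes, config, 19)
    sam = tmp_path / "truth.sam"
    sim.write_truth_sam(sam, genome)
    loaded = read_sam(sam)
    assert len(loaded) == len(sim.reads)
    mem = sim.alignments()
    for read_id, aln in loaded.items():
        truth = mem[read_id]
        assert aln.mapped == truth.mapped
        if aln.mapped:
            assert (aln.chrom, aln.pos, aln.strand) == (
                truth.chrom, truth.pos, truth.strand,
            )
            assert aln.fully_aligned


def test_junction_crossing_reads_marked_unaligned(probe_setup):
    genome, probes = probe_setup
    derived = implant_variants(genome, [Deletion("chr1", 2200, 4000)])
    # the "+" probe at 2000-2040 now reads straight into the junction
    config = SimConfig(
        n_fragments=20_000, read1_len=300, capture_efficiency=0.5,
        efficiency_sigma=0.0,
    )
    sim = simulate_capture(
        [SourceGenome("tumor", derived.genome, 1.0, derived.lift)],
        probes, config, 23,
    )
    plus_reads = [r for r in sim.reads if r.probe_id == probes[0].probe_id]
    assert plus_reads
    # Read 1 spans derived positions 2040..2340, crossing the junction at 2200
    crossing = [r for r in plus_reads if r.src_pos < 2200 < r.src_pos + len(r.read1)]
    assert crossing
    assert all(not r.fully_aligned for r in crossing)
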