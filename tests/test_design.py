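"""Probe placement gates, window search, oligo assembly and catalogs."""

import pytest
from hypothesis import given, settings, strategies as st

from osseq.design import (
    CONTAINS_N, GC_RANGE, KMER_NOT_UNIQUE, REPEAT_ADJACENT, SNP_IN_TERMINAL_10,
    BreakpointTarget, DesignParams, TargetRegion, assemble_oligo,
    candidate_passes_filters, catalog_to_frame, design_for_breakpoint,
    design_for_interval, design_for_snp, finalize_catalog, gc_content,
    interval_windows, load_universal_segments, make_candidate, probe_density,
    read_catalog, write_catalog,
)
from osseq.genome import Genome, reverse_complement
from osseq.kmer import classify_positions
from osseq.simulate import simulate_genome


@pytest.fixture(scope="module")
def clean():
    genome, _ = simulate_genome(5000, 7)
    track = classify_positions(genome, 20, 1)
    return genome, track


def test_gc_content_values():
    assert gc_content("ACGT") == 0.5
    assert gc_content("AAAA") == 0.0
    seq = "G" * 11 + "A" * 29  # 11 G/C in a 40-mer
    assert gc_content(seq) == pytest.approx(0.275)
    params = DesignParams()
    assert not (params.gc_min <= gc_content(seq) <= params.gc_max)


def test_gc_content_rejects_n_and_empty():
    with pytest.raises(ValueError):
        gc_content("ACGN")
    with pytest.raises(ValueError):
        gc_content("")


def test_clean_candidate_passes(clean):
    genome, track = clean
    cand = make_candidate(genome, "chr1", 1000, "+")
    decision = candidate_passes_filters(cand, track, None)
    assert decision.passed and decision.failures == ()


def test_snp_near_extension_end_fails_terminal10(clean):
    genome, track = clean
    cand = make_candidate(genome, "chr1", 1000, "+")
    # SNP 3 bases from the extension end (anchor_end - 3)
    snps = {("chr1", cand.anchor_end - 3)}
    decision = candidate_passes_filters(cand, track, snps)
    assert SNP_IN_TERMINAL_10 in decision.failures
    # same SNP on the far side of a "-" probe is harmless
    cand_minus = make_candidate(genome, "chr1", 1000, "-")
    assert candidate_passes_filters(cand_minus, track, snps).passed


def test_repetitive_terminal_kmer_fails_uniqueness():
    genome, _ = simulate_genome(2000, 9)
    seq = genome["chr1"].seq
    seq = seq[:1000] + "AT" * 60 + seq[1120:]
    g = Genome.from_dict({"chr1": seq})
    track = classify_positions(g, 20, 1)
    cand = make_candidate(g, "chr1", 1040, "+")  # terminal 20-mer inside the tract
    decision = candidate_passes_filters(cand, track, None)
    assert KMER_NOT_UNIQUE in decision.failures


def test_repeat_adjacent_on_extension_side():
    genome, _ = simulate_genome(2000, 13)
    seq = genome["chr1"].seq
    seq = seq[:1000] + "CA" * 60 + seq[1120:]
    g = Genome.from_dict({"chr1": seq})
    track = classify_positions(g, 20, 1)
    # "+" probe ending right before the tract: extension side is repetitive
    cand = make_candidate(g, "chr1", 955, "+")
    decision = candidate_passes_filters(cand, track, None)
    assert REPEAT_ADJACENT in decision.failures


def test_candidate_with_n_reports_contains_n():
    genome, _ = simulate_genome(200, 15)
    seq = genome["chr1"].seq[:100] + "N" + genome["chr1"].seq[101:]
    g = Genome.from_dict({"chr1": seq})
    track = classify_positions(g, 20, 1)
    cand = make_candidate(g, "chr1", 80, "+")
    assert CONTAINS_N in candidate_passes_filters(cand, track, None).failures


def test_interval_design_double_stranded_and_sound(clean):
    genome, track = clean
    target = TargetRegion("chr1", 2300, 2700, "EXON", "exon1")
    res = design_for_interval(target, genome, track)
    plus = [p for p in res.probes if p.strand == "+"]
    minus = [p for p in res.probes if p.strand == "-"]
    assert len(plus) >= 2 and len(minus) >= 2
    assert res.gaps == []
    assert abs(len(plus) - len(minus)) <= 1
    for p in res.probes:
        assert candidate_passes_filters(p, track, None).passed
        # orientation: extension reads into the target
        if p.strand == "+":
            assert p.target_seq_40 == genome["chr1"].seq[p.anchor_start:p.anchor_end]
        else:
            assert p.target_seq_40 == reverse_complement(
                genome["chr1"].seq[p.anchor_start:p.anchor_end]
            )


def test_flanking_probe_distance_window(clean):
    genome, track = clean
    target = TargetRegion("chr1", 2400, 2550, "EXON", "small")
    res = design_for_interval(target, genome, track)
    fmin, fmax = DesignParams().flank_window
    up = [p for p in res.probes if p.strand == "+" and p.anchor_end <= target.start]
    down = [p for p in res.probes if p.strand == "-" and p.anchor_start >= target.end]
    assert up and down
    assert all(fmin <= target.start - p.anchor_end <= fmax for p in up)
    assert all(fmin <= p.anchor_start - target.end <= fmax for p in down)


def test_homopolymer_flank_produces_design_gap():
    genome, _ = simulate_genome(3000, 21)
    seq = genome["chr1"].seq
    # drown the upstream flank of the target in homopolymer
    seq = seq[:700] + "A" * 400 + seq[1100:]
    g = Genome.from_dict({"chr1": seq})
    track = classify_positions(g, 20, 1)
    target = TargetRegion("chr1", 1150, 1300, "EXON", "t")
    res = design_for_interval(target, g, track)
    gap_strands = {gap.strand for gap in res.gaps}
    assert "+" in gap_strands  # upstream "+" window unfillable


def test_tiling_spacing_within_tolerance(clean):
    genome, track = clean
    params = DesignParams()
    target = TargetRegion("chr1", 1500, 3500, "LOCUS", "big")
    res = design_for_interval(target, genome, track, params=params)
    for strand in "+-":
        anchors = sorted(
            p.anchor_start for p in res.probes if p.strand == strand
        )
        gaps = [b - a for a, b in zip(anchors, anchors[1:])]
        assert gaps, strand
        assert all(
            params.tile_spacing - params.tile_tolerance
            <= g
            <= params.tile_spacing + params.tile_tolerance
            for g in gaps
        )


def test_snp_design_two_probes_opposite_strands(clean):
    genome, track = clean
    res = design_for_snp(("chr1", 2500), genome, track)
    assert len(res.probes) == 2 and not res.gaps
    strands = sorted(p.strand for p in res.probes)
    assert strands == ["+", "-"]
    for p in res.probes:
        t10_start, t10_end = p.terminal10_interval()
        assert not (t10_start <= 2500 < t10_end)


def test_snp_near_contig_end_yields_gap(clean):
    genome, track = clean
    pos = 5000 - 30
    res = design_for_snp(("chr1", pos), genome, track)
    assert len(res.probes) == 1 and len(res.gaps) == 1
    assert res.probes[0].strand == "+"


def test_snp_inside_repeat_yields_two_gaps():
    genome, _ = simulate_genome(3000, 33)
    seq = genome["chr1"].seq
    seq = seq[:1000] + "AT" * 500 + seq[2000:]
    g = Genome.from_dict({"chr1": seq})
    track = classify_positions(g, 20, 1)
    res = design_for_snp(("chr1", 1500), g, track)
    assert res.probes == [] and len(res.gaps) == 2


def test_breakpoint_probes_flank_junction(clean):
    genome, track = clean
    sv = BreakpointTarget("chr1", 2400, "chr1", 2600, "DEL", "sv1")
    res = design_for_breakpoint(sv, genome, track)
    assert len(res.probes) == 4 and not res.gaps
    dmin, dmax = DesignParams().breakpoint_probe_distance
    for p in res.probes:
        if p.strand == "+":
            d = 2400 - p.anchor_end
        else:
            d = p.anchor_start - 2600
        assert dmin <= d <= dmax
    assert sorted(p.strand for p in res.probes) == ["+", "+", "-", "-"]


def test_breakpoint_near_contig_end_yields_gaps(clean):
    genome, track = clean
    sv = BreakpointTarget("chr1", 100, "chr1", 4900, "DEL", "sv_edge")
    res = design_for_breakpoint(sv, genome, track)
    assert len(res.probes) < 4
    assert len(res.probes) + len(res.gaps) == 4


def test_breakpoint_repeat_side_absent():
    genome, _ = simulate_genome(4000, 41)
    seq = genome["chr1"].seq
    seq = seq[:2100] + "AG" * 300 + seq[2700:]  # repeats downstream of pos2
    g = Genome.from_dict({"chr1": seq})
    track = classify_positions(g, 20, 1)
    sv = BreakpointTarget("chr1", 1700, "chr1", 2060, "DEL", "svr")
    res = design_for_breakpoint(sv, g, track)
    assert all(p.strand == "+" for p in res.probes)
    assert any(gap.strand == "-" for gap in res.gaps)


def test_assemble_oligo_lengths_and_round_trip():
    probe = make_candidate(Genome.from_dict({"c": "T" * 100}), "c", 10, "+")
    mid, tail = "A" * 37, "C" * 24
    oligo = assemble_oligo(probe, mid, tail)
    assert len(oligo) == 101 and oligo.startswith("T" * 40)
    assert oligo[:40] == probe.target_seq_40
    with pytest.raises(ValueError):
        assemble_oligo(probe, "A" * 36, tail)


def test_default_universal_segments_sum_to_61():
    segs = load_universal_segments()
    assert len(segs["universal_mid"]) + len(segs["p7_complement"]) == 61


def test_probe_density(clean):
    genome, track = clean
    targets = [TargetRegion("chr1", 0, 1000, "EXON", "t")]
    probes = [make_candidate(genome, "chr1", i * 100, "+") for i in range(10)]
    assert probe_density(probes, targets) == 10.0
    assert probe_density([], targets) == 0.0
    with pytest.raises(ValueError):
        probe_density(probes, [])


def test_design_is_deterministic(clean):
    genome, track = clean
    target = TargetRegion("chr1", 1500, 3500, "LOCUS", "big")
    frames = []
    for _ in range(2):
        res = design_for_interval(target, genome, track)
        finalize_catalog(res.probes)
        frames.append(catalog_to_frame(res.probes))
    assert frames[0].equals(frames[1])


def test_catalog_tsv_round_trip(tmp_path, clean):
    genome, track = clean
    res = design_for_interval(TargetRegion("chr1", 2300, 2700, "EXON", "x"), genome, track)
    finalize_catalog(res.probes)
    path = tmp_path / "probes.tsv"
    write_catalog(res.probes, path)
    loaded = read_catalog(path)
    assert [p.probe_id for p in loaded] == [p.probe_id for p in res.probes]
    assert all(a.oligo_101 == b.oligo_101 for a, b in zip(loaded, res.probes))
    assert all(len(p.oligo_101) == 101 for p in loaded)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(min_value=0, max_value=4940))
def test_candidate_gc_matches_gc_content(anchor):
    genome, _ = simulate_genome(5000, 7)
    cand = make_candidate(genome, "chr1", anchor, "+")
    assert cand.gc_fraction == pytest.approx(gc_content(cand.target_seq_40))
    # strand does not change anchor GC
    cand_m = make_candidate(genome, "chr1", anchor, "-")
    assert cand_m.gc_fraction == cand.gc_fraction
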