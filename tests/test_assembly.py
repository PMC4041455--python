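"""SV candidate filtering, read filtering, de Bruijn assembly and
contig split-validation."""

import numpy as np
import pytest

from osseq.assembly import (
    FULLY_REFERENCE, GERMLINE, NO_SPLIT, PRIMER2, PRIMER2_RC, WRONG_CHROM,
    AssemblyRead, BreakpointCall, Contig, ContigRejection, SvCandidate,
    assemble_locus, build_locus_groups, filter_reads_for_assembly,
    filter_sv_candidates, validate_contig,
)
from osseq.genome import Genome, reverse_complement
from osseq.qc import AlignedRead
from osseq.simulate import simulate_genome

from oracles import overlap_walk


def _cand(support, chroms=("chr2", "chr2"), anchor_len=20):
    return SvCandidate(chroms[0], 1000, chroms[1], 5000, "DEL", support, anchor_len)


class TestSvCandidateFilter:
    def test_single_tumor_support_thresholds(self):
        kept = filter_sv_candidates(
            [_cand({"t1": 25}), _cand({"t1": 12})],
            sex="female", tumor_samples=["t1", "t2"], normal_samples=["n"],
        )
        assert len(kept) == 1 and kept[0].support == {"t1": 25}

    def test_shared_support_rescues_weak_candidates(self):
        kept = filter_sv_candidates(
            [_cand({"t1": 12, "t2": 12})],
            sex="female", tumor_samples=["t1", "t2"],
        )
        assert len(kept) == 1

    def test_germline_subtraction(self):
        kept = filter_sv_candidates(
            [_cand({"t1": 30, "n": 4})],
            sex="female", tumor_samples=["t1"], normal_samples=["n"],
        )
        assert kept == []

    def test_chry_in_female_dropped(self):
        kept = filter_sv_candidates(
            [_cand({"t1": 30}, chroms=("chrY", "chr2"))],
            sex="female", tumor_samples=["t1"],
        )
        assert kept == []
        kept_male = filter_sv_candidates(
            [_cand({"t1": 30}, chroms=("chrY", "chr2"))],
            sex="male", tumor_samples=["t1"],
        )
        assert len(kept_male) == 1

    def test_repeat_mask_and_anchor_length(self):
        mask = {"chr2": [(990, 1010)]}
        kept = filter_sv_candidates(
            [_cand({"t1": 30})], sex="male", tumor_samples=["t1"], repeat_mask=mask
        )
        assert kept == []
        kept2 = filter_sv_candidates(
            [_cand({"t1": 30}, anchor_len=10)], sex="male", tumor_samples=["t1"]
        )
        assert kept2 == []


def test_locus_grouping_partitions_and_conserves():
    reads = [
        ("tumor", "r1", "p1", "ACGT", "IIII"),
        ("tumor", "r2", "p2", "ACGT", "IIII"),
        ("normal", "r3", "p1", "ACGT", "IIII"),
        ("tumor", "r4", "p9", "ACGT", "IIII"),  # probe of another locus
        ("tumor", "r5", "px", "ACGT", "IIII"),  # unknown probe: discarded
    ]
    groups = build_locus_groups(reads, {"p1": "L1", "p2": "L1", "p9": "L2"})
    assert groups["L1"].n_reads("tumor") == 2
    assert groups["L1"].n_reads("normal") == 1
    assert groups["L2"].n_reads("tumor") == 1
    total = sum(
        g.n_reads(s) for g in groups.values() for s in ("tumor", "normal")
    )
    assert total == 4


class TestReadFilter:
    def _read(self, seq, qual_char="I", rid="r"):
        return AssemblyRead(rid, seq, qual_char * len(seq))

    def test_fully_aligned_read_removed(self):
        aln = {"r": AlignedRead("r", "chr1", 0, "+", 60, 30, fully_aligned=True)}
        assert filter_reads_for_assembly([self._read("ACGT" * 10)], aln) == []

    def test_primer2_and_its_rc_removed(self):
        reads = [
            self._read("AAAA" + PRIMER2 + "GGGG", rid="a"),
            self._read("AAAA" + PRIMER2_RC + "GGGG", rid="b"),
        ]
        assert filter_reads_for_assembly(reads, {}) == []

    def test_low_quality_removed_and_junction_read_kept(self):
        # mean Phred 20 ('5') fails the >25 gate; 'I' (40) passes
        low = self._read("ACGT" * 10, qual_char="5", rid="low")
        good = self._read("ACGT" * 10, rid="good")
        aln = {"good": AlignedRead("good", None, 0, "+", 0, 40, False, mapped=False)}
        kept = filter_reads_for_assembly([low, good], aln)
        assert [r.read_id for r in kept] == ["good"]


def _windows(seq, w, copies):
    return [seq[i : i + w] for i in range(len(seq) - w + 1)] * copies


class TestAssembleLocus:
    def test_single_path_reconstructed(self):
        genome, _ = simulate_genome(70, 101)
        source = genome["chr1"].seq
        reads = _windows(source, 30, 4)
        contigs = assemble_locus(reads, k=19, min_contig_len=50, min_coverage=4)
        assert len(contigs) == 1
        assert contigs[0].sequence in (source, reverse_complement(source))

    def test_coverage_gate_suppresses_thin_contigs(self):
        # two copies of the source give k-mer coverage 2, below the gate of 4
        genome, _ = simulate_genome(70, 101)
        reads = [genome["chr1"].seq] * 2
        assert assemble_locus(reads, k=19, min_contig_len=50, min_coverage=4) == []
        assert len(assemble_locus(reads * 2, k=19, min_contig_len=50, min_coverage=4)) == 1

    def test_two_sources_give_two_contigs(self):
        g1, _ = simulate_genome(80, 7)
        g2, _ = simulate_genome(80, 8)
        reads = _windows(g1["chr1"].seq, 30, 4) + _windows(g2["chr1"].seq, 30, 4)
        contigs = assemble_locus(reads, k=19, min_contig_len=50, min_coverage=4)
        assert len(contigs) == 2
        seqs = {c.sequence for c in contigs}
        for src in (g1["chr1"].seq, g2["chr1"].seq):
            assert src in seqs or reverse_complement(src) in seqs

    def test_no_reads_gives_empty_list(self):
        assert assemble_locus([], k=19) == []

    def test_matches_overlap_walk_oracle_on_simple_paths(self):
        rng = np.random.default_rng(555)
        for trial in range(20):
            length = int(rng.integers(90, 200))
            genome, _ = simulate_genome(length, int(rng.integers(0, 2**31)))
            source = genome["chr1"].seq
            expected = overlap_walk([source], 19)
            if expected is None:
                continue  # not a simple path; out of the oracle's scope
            reads = _windows(source, 40, 4)
            contigs = assemble_locus(reads, k=19, min_contig_len=50, min_coverage=4)
            assert len(contigs) == 1
            assert contigs[0].sequence in (expected, reverse_complement(expected))


@pytest.fixture(scope="module")
def reference():
    genome, _ = simulate_genome(8000, 202)
    return genome


class TestValidateContig:
    def test_deletion_like_junction_called(self, reference):
        seq = reference["chr1"].seq
        contig = seq[100:160] + seq[5000:5060]
        res = validate_contig(contig, reference, expected_chrom="chr1")
        assert isinstance(res, BreakpointCall)
        assert (res.junction.pos1, res.junction.pos2) == (160, 5000)
        assert res.junction.sv_type == "DEL"

    def test_inversion_junction_called(self, reference):
        from osseq.simulate import junction_is_ambiguous

        seq = reference["chr1"].seq
        s, e = 160, 5060
        while junction_is_ambiguous(seq, "INV", s, e):
            e += 1
        contig = seq[s - 60 : s] + reverse_complement(seq[e - 60 : e])
        res = validate_contig(contig, reference, expected_chrom="chr1")
        assert isinstance(res, BreakpointCall)
        assert (res.junction.pos1, res.junction.pos2) == (s, e)
        assert res.junction.sv_type == "INV"

    def test_reference_contig_rejected(self, reference):
        seq = reference["chr1"].seq
        res = validate_contig(seq[300:420], reference)
        assert isinstance(res, ContigRejection) and res.reason == FULLY_REFERENCE

    def test_random_contig_has_no_split(self, reference):
        rng = np.random.default_rng(9)
        noise = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
        res = validate_contig(noise, reference)
        assert isinstance(res, ContigRejection) and res.reason == NO_SPLIT

    def test_wrong_chromosome_rejected(self):
        g1, _ = simulate_genome(3000, 11)
        g2, _ = simulate_genome(3000, 12)
        ref = Genome.from_dict(
            {"chr1": g1["chr1"].seq, "chr2": g2["chr1"].seq}
        )
        contig = ref["chr2"].seq[100:160] + ref["chr2"].seq[2000:2060]
        res = validate_contig(contig, ref, expected_chrom="chr1")
        assert isinstance(res, ContigRejection) and res.reason == WRONG_CHROM

    def test_germline_junction_rejected(self, reference):
        seq = reference["chr1"].seq
        contig = seq[100:160] + seq[5000:5060]
        res = validate_contig(
            contig, reference, normal_contigs=[contig], expected_chrom="chr1"
        )
        assert isinstance(res, ContigRejection) and res.reason == GERMLINE

    def test_microhomology_reported_and_leftmost_split(self, reference):
        seq = reference["chr1"].seq
        # force 1 base of microhomology across the junction
        s, e = 200, 6000
        base = seq[s]
        mod = seq[:e] + base + seq[e + 1 :]
        ref = Genome.from_dict({"chr1": mod})
        contig = mod[s - 50 : s] + mod[e : e + 50]
        res = validate_contig(contig, ref, expected_chrom="chr1")
        assert isinstance(res, BreakpointCall)
        assert res.homology_len >= 1
        # leftmost representation: prefix cannot extend left of s
        assert res.junction.pos1 <= s
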