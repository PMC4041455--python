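"""Synthetic genomes, implanted variants and capture-read simulation.

Everything the other modules consume can be generated here at desk
scale: reference genomes with optional repeat tracts, derived genomes
carrying SNVs/indels/SVs with an exact coordinate lift map, and paired
reads from a model of flow-cell capture.  The capture model follows the
assay geometry: fragments (~500 b) are drawn at random from each source
genome in proportion to its mixture weight; a fragment is captured by a
probe, with that probe's efficiency, when it contains the probe's
40-base anchor site and extends beyond it on the extension side.  Read
1 starts at the first genomic base past the probe footprint and reads
in the extension direction; Read 2 starts with the probe's synthetic
40-mer.  Every read carries provenance, and a truth SAM can be written
directly from provenance without running an aligner.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import pysam
import yaml

from .assembly import Junction
from .design import PrimerProbe
from .genome import Genome, GenomeSequence, as_genome, complement, reverse_complement
from .qc import AlignedRead

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Capture-simulation parameters.

    Defaults follow the assay conditions: ~500 b fragment peak, 80x40
    paired-end reads, and a mean capture efficiency of 4.9% of eligible
    library fragments per probe.  ``efficiency_sigma`` spreads per-probe
    efficiencies lognormally around the mean to emulate probe-to-probe
    yield variation; 0 gives identical efficiencies.
    """

    n_fragments: int = 50_000
    fragment_mean: float = 500.0
    fragment_sd: float = 60.0
    read1_len: int = 80
    read2_len: int = 40
    capture_efficiency: float = 0.049
    efficiency_sigma: float = 0.25
    error_rate: float = 0.001
    base_quality: int = 35
    min_fragment_len: int = 100
    min_read1_len: int = 20

    def __post_init__(self):
        if self.n_fragments <= 0 or self.read1_len <= 0 or self.read2_len <= 0:
            raise ValueError("all lengths/counts must be positive")
        if not (0 <= self.capture_efficiency <= 1):
            raise ValueError("capture_efficiency must be in [0,1]")
        if not (0 <= self.error_rate <= 1):
            raise ValueError("error_rate must be in [0,1]")


def simulate_genome(
    length: int,
    seed: Union[int, np.random.Generator],
    name: str = "chr1",
    repeat_fraction: float = 0.0,
    repeat_unit: str = "AT",
    repeat_tract_len: int = 120,
) -> Tuple[Genome, List[Tuple[str, int, int]]]:
    """Uniform-random genome with optional embedded tandem-repeat tracts.

    Returns the genome plus BED-style (chrom, start, end) annotations of
    the implanted repeat tracts (empty when ``repeat_fraction`` is 0).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = BASES[rng.integers(0, 4, size=length)]
    repeats: List[Tuple[str, int, int]] = []
    if repeat_fraction > 0:
        n_tracts = max(1, int(round(length * repeat_fraction / repeat_tract_len)))
        unit = repeat_unit.upper().encode()
        tract = (unit * (repeat_tract_len // len(unit) + 1))[:repeat_tract_len]
        taken: List[Tuple[int, int]] = []
        attempts = 0
        while len(repeats) < n_tracts and attempts < 50 * n_tracts:
            attempts += 1
            s = int(rng.integers(0, max(1, length - repeat_tract_len)))
            e = s + repeat_tract_len
            if any(s < te and e > ts for ts, te in taken):
                continue
            arr[s:e] = np.frombuffer(tract, dtype=np.uint8)
            taken.append((s, e))
            repeats.append((name, s, e))
        repeats.sort(key=lambda r: r[1])
    return Genome([GenomeSequence(name, arr.tobytes().decode())]), repeats


# ---------------------------------------------------------------------------
# variant implantation


@dataclass(frozen=True)
class Snv:
    chrom: str
    pos: int
    alt: str


@dataclass(frozen=True)
class Insertion:
    chrom: str
    pos: int
    seq: str


@dataclass(frozen=True)
class Deletion:
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class Inversion:
    chrom: str
    start: int
    end: int


Variant = Union[Snv, Insertion, Deletion, Inversion]


@dataclass(frozen=True)
class LiftSegment:
    der_start: int
    der_end: int
    ref_start: int
    ref_end: int
    strand: str  # '+', '-' (inverted) or '.' (inserted, no reference)


class LiftMap:
    """Piecewise map between derived and reference coordinates of one
    chromosome."""

    def __init__(self, segments: Sequence[LiftSegment]):
        self.segments = list(segments)

    def contiguous_ref_interval(
        self, der_start: int, der_end: int
    ) -> Optional[Tuple[int, int, str]]:
        """Reference interval for a derived interval, or None when the
        interval crosses a junction (and therefore has no contiguous
        reference image)."""
        for seg in self.segments:
            if seg.der_start <= der_start and der_end <= seg.der_end:
                if seg.strand == ".":
                    return None
                off_lo = der_start - seg.der_start
                off_hi = der_end - seg.der_start
                if seg.strand == "+":
                    return seg.ref_start + off_lo, seg.ref_start + off_hi, "+"
                return seg.ref_end - off_hi, seg.ref_end - off_lo, "-"
        return None

    def ref_to_derived(self, pos: int) -> Optional[int]:
        for seg in self.segments:
            if seg.strand == "." or not (seg.ref_start <= pos < seg.ref_end):
                continue
            if seg.strand == "+":
                return seg.der_start + (pos - seg.ref_start)
            return seg.der_start + (seg.ref_end - 1 - pos)
        return None


@dataclass
class DerivedGenome:
    genome: Genome
    lift: Dict[str, LiftMap]
    junctions: List[Junction]


def implant_variants(
    genome: Union[Genome, GenomeSequence, Mapping[str, str]],
    variants: Sequence[Variant],
) -> DerivedGenome:
    """Apply SNVs/indels/SVs to a genome, tracking coordinates and truth.

    Variants must be non-overlapping after sorting (SNVs may not fall
    inside a structural variant's interval).  Deletion and inversion
    junction coordinates are recorded as truth.
    """
    ref = as_genome(genome)
    by_chrom: Dict[str, List[Variant]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    out_seqs: List[GenomeSequence] = []
    lifts: Dict[str, LiftMap] = {}
    junctions: List[Junction] = []
    for name, rec in ref.items():
        chrom_vars = by_chrom.get(name, [])
        seq = bytearray(rec.seq.encode())
        structural: List[Variant] = []
        sv_spans: List[Tuple[int, int]] = []
        for v in chrom_vars:
            if isinstance(v, Snv):
                continue
            if isinstance(v, Insertion):
                structural.append(v)
                sv_spans.append((v.pos, v.pos))
            else:
                structural.append(v)
                sv_spans.append((v.start, v.end))
        for v in chrom_vars:
            if isinstance(v, Snv):
                if any(s <= v.pos < e for s, e in sv_spans):
                    raise ValueError("SNV inside a structural-variant interval")
                if len(v.alt) != 1 or v.alt not in "ACGT":
                    raise ValueError("SNV alt must be a single ACGT base")
                seq[v.pos] = ord(v.alt)
        structural.sort(key=lambda v: v.pos if isinstance(v, Insertion) else v.start)
        pieces: List[bytes] = []
        segments: List[LiftSegment] = []
        cursor = 0
        der = 0

        def emit_identity(upto: int) -> None:
            nonlocal cursor, der
            if upto > cursor:
                pieces.append(bytes(seq[cursor:upto]))
                segments.append(LiftSegment(der, der + upto - cursor, cursor, upto, "+"))
                der += upto - cursor
                cursor = upto

        for v in structural:
            start = v.pos if isinstance(v, Insertion) else v.start
            if start < cursor:
                raise ValueError("overlapping structural variants")
            emit_identity(start)
            if isinstance(v, Deletion):
                junctions.append(Junction(name, v.start, name, v.end, "DEL"))
                cursor = v.end
            elif isinstance(v, Inversion):
                segment = bytes(seq[v.start : v.end])
                pieces.append(reverse_complement(segment.decode()).encode())
                segments.append(
                    LiftSegment(der, der + (v.end - v.start), v.start, v.end, "-")
                )
                der += v.end - v.start
                cursor = v.end
                junctions.append(Junction(name, v.start, name, v.end, "INV"))
            else:  # Insertion
                ins = v.seq.upper().encode()
                pieces.append(ins)
                segments.append(LiftSegment(der, der + len(ins), v.pos, v.pos, "."))
                der += len(ins)
                cursor = v.pos
        emit_identity(len(seq))
        out_seqs.append(GenomeSequence(name, b"".join(pieces).decode()))
        lifts[name] = LiftMap(segments)
    return DerivedGenome(Genome(out_seqs), lifts, junctions)


def junction_is_ambiguous(ref_seq: str, kind: str, start: int, end: int) -> bool:
    """True when junction microhomology would let the breakpoint shift.

    Used when placing fixture SVs so that "exact" junction recovery is
    well defined: a deletion junction can shift by one base when the
    bases flanking the removed segment repeat across it; an inversion
    junction shifts when a flanking base equals the complement of its
    mirror base.
    """
    if kind == "DEL":
        return ref_seq[start] == ref_seq[end] or ref_seq[start - 1] == ref_seq[end - 1]
    if kind == "INV":
        return (
            ref_seq[start] == complement(ref_seq[end - 1])
            or ref_seq[start - 1] == complement(ref_seq[end])
        )
    return False


# ---------------------------------------------------------------------------
# capture simulation


@dataclass
class SourceGenome:
    """One mixture component: a genome, its weight, and (for derived
    genomes) the lift back to the reference frame."""

    name: str
    genome: Genome
    weight: float
    lift: Optional[Dict[str, LiftMap]] = None


@dataclass
class SimRead:
    read_id: str
    read1: str
    qual1: str
    read2: str
    qual2: str
    probe_id: str
    source: str
    tag: Optional[str]
    # provenance in the source-genome frame
    src_chrom: str
    src_pos: int
    src_strand: str
    frag_start: int
    frag_end: int
    # truth in the reference frame (None when the read crosses a junction)
    ref_chrom: Optional[str]
    ref_pos: Optional[int]
    ref_strand: Optional[str]
    fully_aligned: bool


@dataclass
class SimResult:
    sample: str
    reads: List[SimRead]
    probe_efficiencies: Dict[str, float]
    config: SimConfig

    def truth_frame(self) -> pd.DataFrame:
        rows = [
            {
                "read_id": r.read_id,
                "probe_id": r.probe_id,
                "source": r.source,
                "src_chrom": r.src_chrom,
                "src_pos": r.src_pos,
                "src_strand": r.src_strand,
                "frag_start": r.frag_start,
                "frag_end": r.frag_end,
                "ref_chrom": r.ref_chrom if r.ref_chrom is not None else "",
                "ref_pos": -1 if r.ref_pos is None else r.ref_pos,
                "ref_strand": r.ref_strand or "",
                "fully_aligned": r.fully_aligned,
            }
            for r in self.reads
        ]
        return pd.DataFrame(rows)

    def alignments(self) -> Dict[str, AlignedRead]:
        """Truth alignments as in-memory records (no aligner involved)."""
        out = {}
        for r in self.reads:
            out[r.read_id] = AlignedRead(
                read_id=r.read_id,
                chrom=r.ref_chrom,
                pos=r.ref_pos if r.ref_pos is not None else 0,
                strand=r.ref_strand or "+",
                mapq=60 if r.fully_aligned else 0,
                aln_len=len(r.read1),
                fully_aligned=r.fully_aligned,
                mapped=r.fully_aligned,
                seq=r.read1,
                qual=r.qual1,
            )
        return out

    def write_fastq(self, path1: Union[str, Path], path2: Union[str, Path]) -> None:
        with open(path1, "w") as f1, open(path2, "w") as f2:
            for r in self.reads:
                tag = f" tag:{r.tag}" if r.tag else ""
                f1.write(f"@{r.read_id}/1{tag}\n{r.read1}\n+\n{r.qual1}\n")
                f2.write(f"@{r.read_id}/2{tag}\n{r.read2}\n+\n{r.qual2}\n")

    def write_truth_sam(
        self, path: Union[str, Path], reference: Union[Genome, Mapping[str, str]]
    ) -> None:
        """Truth SAM for Read 1: junction-crossing reads are unmapped."""
        ref = as_genome(reference)
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": name, "LN": len(rec.seq)} for name, rec in ref.items()],
        }
        names = list(ref)
        with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
            for r in self.reads:
                a = pysam.AlignedSegment()
                a.query_name = r.read_id
                if r.fully_aligned and r.ref_chrom is not None:
                    a.reference_id = names.index(r.ref_chrom)
                    a.reference_start = r.ref_pos
                    a.mapping_quality = 60
                    a.cigarstring = f"{len(r.read1)}M"
                    if r.ref_strand == "-":
                        a.flag = 16
                        a.query_sequence = reverse_complement(r.read1)
                        a.query_qualities = pysam.qualitystring_to_array(r.qual1[::-1])
                    else:
                        a.flag = 0
                        a.query_sequence = r.read1
                        a.query_qualities = pysam.qualitystring_to_array(r.qual1)
                else:
                    a.flag = 4
                    a.reference_id = -1
                    a.reference_start = -1
                    a.mapping_quality = 0
                    a.query_sequence = r.read1
                    a.query_qualities = pysam.qualitystring_to_array(r.qual1)
                fh.write(a)


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0 or not seq:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    arr = bytearray(seq.encode())
    positions = rng.choice(len(seq), size=n_err, replace=False)
    for p in positions:
        current = arr[p]
        choices = [b for b in b"ACGT" if b != current]
        arr[p] = choices[int(rng.integers(0, len(choices)))]
    return arr.decode()


def _probe_sites(genome: Genome, probe: PrimerProbe) -> List[Tuple[str, int, str]]:
    """Occurrences of the probe 40-mer in a genome, either orientation.

    A forward occurrence extends rightward from the site end; a
    reverse-complement occurrence extends leftward from the site start.
    """
    sites = []
    t40 = probe.target_seq_40
    rc = reverse_complement(t40)
    for name, rec in genome.items():
        for query, orient in ((t40, "+"), (rc, "-")):
            start = rec.seq.find(query)
            while start != -1:
                sites.append((name, start, orient))
                start = rec.seq.find(query, start + 1)
    return sites


def simulate_capture(
    sources: Sequence[SourceGenome],
    probes: Sequence[PrimerProbe],
    config: SimConfig,
    seed: Union[int, np.random.Generator],
    sample: str = "S",
    tag: Optional[str] = None,
) -> SimResult:
    """Simulate flow-cell capture of a (possibly mixed) sample.

    Fragments are apportioned to sources by weight, drawn uniformly
    along each chromosome with Normal(fragment_mean, fragment_sd)
    lengths, and captured per probe site with the probe's efficiency
    whenever they contain the 40-base site plus at least
    ``min_read1_len`` bases of extension room.  Output is fully
    deterministic for a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not probes:
        raise ValueError("no probes supplied")
    weights = np.array([s.weight for s in sources], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("source weights must sum to a positive value")
    weights = weights / weights.sum()

    ordered_probes = sorted(probes, key=lambda p: p.probe_id)
    if config.efficiency_sigma > 0:
        sigma = config.efficiency_sigma
        draws = rng.lognormal(-0.5 * sigma**2, sigma, size=len(ordered_probes))
        effs = np.clip(config.capture_efficiency * draws, 0.0, 1.0)
    else:
        effs = np.full(len(ordered_probes), config.capture_efficiency)
    eff_by_probe = {p.probe_id: float(e) for p, e in zip(ordered_probes, effs)}

    n_by_source = rng.multinomial(config.n_fragments, weights)
    reads: List[SimRead] = []
    serial = 0
    for source, n_frags in zip(sources, n_by_source):
        if n_frags == 0:
            continue
        names = list(source.genome)
        lens = np.array([len(source.genome[c].seq) for c in names], dtype=float)
        p_chrom = lens / lens.sum()
        chrom_idx = rng.choice(len(names), size=n_frags, p=p_chrom)
        u = rng.random(n_frags)
        flen = np.maximum(
            config.min_fragment_len,
            np.round(rng.normal(config.fragment_mean, config.fragment_sd, n_frags)),
        ).astype(np.int64)
        starts = np.floor(u * np.maximum(1, lens[chrom_idx] - flen)).astype(np.int64)
        ends = np.minimum(starts + flen, lens[chrom_idx].astype(np.int64))

        site_cache: Dict[str, List[Tuple[str, int, str]]] = {}
        for pi, probe in enumerate(ordered_probes):
            sites = site_cache.get(probe.probe_id)
            if sites is None:
                sites = _probe_sites(source.genome, probe)
                site_cache[probe.probe_id] = sites
            for chrom_name, s, orient in sites:
                ci = names.index(chrom_name)
                if orient == "+":
                    eligible = (
                        (chrom_idx == ci)
                        & (starts <= s)
                        & (ends >= s + 40 + config.min_read1_len)
                    )
                else:
                    eligible = (
                        (chrom_idx == ci)
                        & (ends >= s + 40)
                        & (starts <= s - config.min_read1_len)
                    )
                draw = rng.random(n_frags)
                captured = np.flatnonzero(eligible & (draw < effs[pi]))
                seq = source.genome[chrom_name].seq
                for fi in captured:
                    frag_s, frag_e = int(starts[fi]), int(ends[fi])
                    if orient == "+":
                        r1s = s + 40
                        r1e = min(r1s + config.read1_len, frag_e)
                        read1 = seq[r1s:r1e]
                        strand = "+"
                        extra = max(0, config.read2_len - 40)
                        read2 = (
                            probe.target_seq_40 + seq[r1s : min(r1s + extra, frag_e)]
                        )[: config.read2_len]
                        aln_lo, aln_hi = r1s, r1e
                    else:
                        r1e_ = s
                        r1s_ = max(r1e_ - config.read1_len, frag_s)
                        read1 = reverse_complement(seq[r1s_:r1e_])
                        strand = "-"
                        extra = max(0, config.read2_len - 40)
                        read2 = (
                            probe.target_seq_40
                            + reverse_complement(seq[max(r1e_ - extra, frag_s) : r1e_])
                        )[: config.read2_len]
                        aln_lo, aln_hi = r1s_, r1e_
                    read1 = _apply_errors(read1, rng, config.error_rate)
                    read2 = _apply_errors(read2, rng, config.error_rate)
                    ref_chrom = ref_pos = ref_strand = None
                    fully = False
                    if source.lift is None:
                        ref_chrom, ref_pos, ref_strand = chrom_name, aln_lo, strand
                        fully = True
                    else:
                        lifted = source.lift[chrom_name].contiguous_ref_interval(
                            aln_lo, aln_hi
                        )
                        if lifted is not None:
                            lo, hi, seg_strand = lifted
                            ref_chrom = chrom_name
                            ref_pos = lo
                            ref_strand = (
                                strand
                                if seg_strand == "+"
                                else ("-" if strand == "+" else "+")
                            )
                            fully = True
                    qual_char = chr(config.base_quality + 33)
                    reads.append(
                        SimRead(
                            read_id=f"{sample}.{serial:07d}",
                            read1=read1,
                            qual1=qual_char * len(read1),
                            read2=read2,
                            qual2=qual_char * len(read2),
                            probe_id=probe.probe_id,
                            source=source.name,
                            tag=tag,
                            src_chrom=chrom_name,
                            src_pos=aln_lo,
                            src_strand=strand,
                            frag_start=frag_s,
                            frag_end=frag_e,
                            ref_chrom=ref_chrom,
                            ref_pos=ref_pos,
                            ref_strand=ref_strand,
                            fully_aligned=fully,
                        )
                    )
                    serial += 1
    return SimResult(
        sample=sample, reads=reads, probe_efficiencies=eff_by_probe, config=config
    )


# ---------------------------------------------------------------------------
# fixture bundle


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def make_fixture_suite(out_dir: Union[str, Path], seed: int = 7) -> Dict[str, str]:
    """Write the canonical small fixture bundle with a digest manifest.

    Repeated invocation with the same seed produces byte-identical
    files.  Returns the manifest mapping (relative path -> sha256).
    """
    from . import workflows  # local import to avoid a cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # clean design fixture
    d = out / "design_clean"
    d.mkdir(exist_ok=True)
    genome, _ = simulate_genome(5000, np.random.default_rng([seed, 1]))
    genome.to_fasta(d / "genome.fa")
    from .design import (
        DesignParams, TargetRegion, design_for_interval, write_catalog,
        write_gap_report,
    )
    from .kmer import classify_positions

    track = classify_positions(genome, 20, 1)
    target = TargetRegion("chr1", 2300, 2700, "EXON", "exon1")
    with open(d / "targets.bed", "w") as fh:
        fh.write("chr1\t2300\t2700\texon1\tEXON\n")
    res = design_for_interval(target, genome, track)
    write_catalog(res.probes, d / "probes.tsv")
    write_gap_report(res.gaps, d / "gaps.tsv")

    # repeat fixture
    r = out / "repeats"
    r.mkdir(exist_ok=True)
    rep_genome, tracts = simulate_genome(
        4000, np.random.default_rng([seed, 2]), repeat_fraction=0.1
    )
    rep_genome.to_fasta(r / "genome.fa")
    with open(r / "repeats.bed", "w") as fh:
        for chrom, s, e in tracts:
            fh.write(f"{chrom}\t{s}\t{e}\ttandem_repeat\n")

    # mixture fixtures
    for spike in (0.05, 0.10, 0.20):
        m = out / f"mixture_{int(spike * 100):02d}"
        m.mkdir(exist_ok=True)
        mix = workflows.mixture_experiment(
            seed=seed + int(spike * 100),
            spike_fraction=spike,
            n_sites=8,
            genome_length=6000,
            n_fragments=12_000,
        )
        mix.reference.to_fasta(m / "genome.fa")
        mix.sites.to_csv(m / "truth_sites.tsv", sep="\t", index=False)
        mix.sim.write_fastq(m / "reads_1.fastq", m / "reads_2.fastq")
        mix.sim.write_truth_sam(m / "truth.sam", mix.reference)

    # tumor/normal SV fixture at 40% cellularity
    sv_dir = out / "sv_tumor_normal"
    sv_dir.mkdir(exist_ok=True)
    sv = workflows.sv_experiment(
        seed=seed,
        genome_length=50_000,
        n_del=2,
        n_inv=1,
        n_fragments=150_000,
    )
    sv.reference.to_fasta(sv_dir / "genome.fa")
    write_catalog(sv.probes, sv_dir / "probes.tsv")
    sv.sim_tumor.write_fastq(sv_dir / "tumor_1.fastq", sv_dir / "tumor_2.fastq")
    sv.sim_normal.write_fastq(sv_dir / "normal_1.fastq", sv_dir / "normal_2.fastq")
    sv.sim_tumor.write_truth_sam(sv_dir / "tumor_truth.sam", sv.reference)
    sv.sim_normal.write_truth_sam(sv_dir / "normal_truth.sam", sv.reference)
    with open(sv_dir / "truth_junctions.tsv", "w") as fh:
        fh.write("kind\tchrom\tpos1\tpos2\tsv_type\n")
        for j in sv.truth_somatic:
            fh.write(f"somatic\t{j.chrom1}\t{j.pos1}\t{j.pos2}\t{j.sv_type}\n")
        for j in sv.truth_germline:
            fh.write(f"germline\t{j.chrom1}\t{j.pos1}\t{j.pos2}\t{j.sv_type}\n")

    manifest: Dict[str, str] = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.yaml":
            manifest[str(path.relative_to(out))] = _sha256(path)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump({"seed": seed, "files": manifest}, fh, sort_keys=True)
    return manifest
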