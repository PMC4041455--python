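"""End-to-end compositions of the library primitives.

These functions wire design -> simulation -> QC/assembly into the
experiments the package is validated on: a gene-panel capture run, a
two-genome mixture titration for minor-allele detection, and a matched
tumor/normal structural-variant experiment resolved to exact junction
coordinates.  They are what the CLI, the example scripts and the
acceptance checks call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .assembly import (
    Junction, LocusGroup, build_locus_groups, resolve_breakpoints,
    resolutions_to_frame, LocusResolution,
)
from .design import (
    BreakpointTarget, DesignGap, DesignParams, PrimerProbe, TargetRegion,
    design_for_breakpoint, design_for_interval, design_for_snp, finalize_catalog,
)
from .genome import Genome, complement
from .kmer import KmerTrack, classify_positions
from .qc import ProbeAssigner, UNASSIGNED, classify_on_target, per_probe_yield, summarize_capture
from .simulate import (
    DerivedGenome, SimConfig, SimResult, Snv, Deletion, Inversion, SourceGenome,
    implant_variants, junction_is_ambiguous, simulate_capture, simulate_genome,
)


# ---------------------------------------------------------------------------
# gene-panel capture QC

@dataclass
class PanelExperiment:
    reference: Genome
    targets: List[TargetRegion]
    probes: List[PrimerProbe]
    gaps: List[DesignGap]
    sim: SimResult
    report: Dict


def panel_experiment(
    seed: int,
    genome_length: int = 20_000,
    n_targets: int = 3,
    target_len: int = 600,
    n_fragments: int = 120_000,
) -> PanelExperiment:
    """Design a small exon-style panel, simulate capture, and QC it."""
    rng = np.random.default_rng([seed, 11])
    genome, _ = simulate_genome(genome_length, rng)
    track = classify_positions(genome, 20, 1)
    span = genome_length // n_targets
    targets = []
    for i in range(n_targets):
        start = i * span + (span - target_len) // 2
        targets.append(TargetRegion("chr1", start, start + target_len, "EXON", f"t{i}"))
    probes: List[PrimerProbe] = []
    gaps: List[DesignGap] = []
    for t in targets:
        res = design_for_interval(t, genome, track)
        probes.extend(res.probes)
        gaps.extend(res.gaps)
    finalize_catalog(probes)
    config = SimConfig(n_fragments=n_fragments)
    sim = simulate_capture(
        [SourceGenome("ref", genome, 1.0)], probes, config,
        np.random.default_rng([seed, 12]), sample="panel",
    )
    report = summarize_capture(
        sim.alignments(), {r.read_id: r.read2 for r in sim.reads}, probes
    )
    return PanelExperiment(genome, targets, probes, gaps, sim, report)


# ---------------------------------------------------------------------------
# mixture titration

@dataclass
class MixtureExperiment:
    spike_fraction: float
    reference: Genome
    probes: List[PrimerProbe]
    sites: pd.DataFrame  # pos, zygosity, alt, expected_af, depth, alt_count, af
    sim: SimResult


def mixture_experiment(
    seed: int,
    spike_fraction: float,
    n_sites: int = 24,
    genome_length: int = 12_000,
    n_fragments: int = 90_000,
    read1_len: int = 250,
    het_fraction: float = 0.84,
) -> MixtureExperiment:
    """Simulate a two-genome mixture and pile up spike-unique SNV sites.

    The spike individual is diploid: heterozygous spike-unique variants
    sit on one haplotype (expected allele fraction s/2 at spike weight
    s), homozygous variants on both (expected fraction s).  Read 1 is
    250 b here so that each probe's reads span its SNP 100-200 b away.
    """
    rng = np.random.default_rng([seed, 21])
    genome, _ = simulate_genome(genome_length, rng)
    seq = genome["chr1"].seq
    lo, hi = 400, genome_length - 400
    spacing = max(60, (hi - lo) // (n_sites + 1))
    positions = [lo + (i + 1) * spacing for i in range(n_sites)]
    zygosity = np.where(rng.random(n_sites) < het_fraction, "het", "hom")
    alts = []
    for p in positions:
        options = [b for b in "ACGT" if b != seq[p]]
        alts.append(options[int(rng.integers(0, 3))])

    track = classify_positions(genome, 20, 1)
    probes: List[PrimerProbe] = []
    kept: List[int] = []
    for i, p in enumerate(positions):
        res = design_for_snp(("chr1", p), genome, track)
        if res.probes:
            probes.extend(res.probes)
            kept.append(i)
    finalize_catalog(probes)

    het_vars = [
        Snv("chr1", positions[i], alts[i]) for i in kept if zygosity[i] == "het"
    ]
    hom_vars = [
        Snv("chr1", positions[i], alts[i]) for i in kept if zygosity[i] == "hom"
    ]
    hap_a = implant_variants(genome, het_vars + hom_vars).genome
    hap_b = implant_variants(genome, hom_vars).genome

    s = spike_fraction
    sources = [
        SourceGenome("background", genome, 1.0 - s),
        SourceGenome("spike_hapA", hap_a, s / 2.0),
        SourceGenome("spike_hapB", hap_b, s / 2.0),
    ]
    config = SimConfig(n_fragments=n_fragments, read1_len=read1_len)
    sim = simulate_capture(
        sources, probes, config, np.random.default_rng([seed, 22]),
        sample=f"mix{int(round(s * 100))}",
    )

    rows = []
    for i in kept:
        p, alt = positions[i], alts[i]
        depth = 0
        alt_count = 0
        for r in sim.reads:
            if not (r.ref_pos is not None and r.ref_pos <= p < r.ref_pos + len(r.read1)):
                continue
            if r.ref_strand == "+":
                base = r.read1[p - r.ref_pos]
            else:
                base = complement(r.read1[r.ref_pos + len(r.read1) - 1 - p])
            depth += 1
            if base == alt:
                alt_count += 1
        expected = s / 2.0 if zygosity[i] == "het" else s
        rows.append(
            {
                "pos": p,
                "zygosity": zygosity[i],
                "ref": seq[p],
                "alt": alt,
                "expected_af": expected,
                "depth": depth,
                "alt_count": alt_count,
                "af": alt_count / depth if depth else 0.0,
            }
        )
    sites = pd.DataFrame(rows)
    return MixtureExperiment(s, genome, probes, sites, sim)


# ---------------------------------------------------------------------------
# tumor/normal SV resolution

@dataclass
class SvExperiment:
    reference: Genome
    truth_somatic: List[Junction]
    truth_germline: List[Junction]
    probes: List[PrimerProbe]
    sim_tumor: SimResult
    sim_normal: SimResult
    resolutions: List[LocusResolution]
    calls: pd.DataFrame
    recovered_somatic: Set[Tuple]
    missed_somatic: Set[Tuple]
    somatic_calls_in_normal: int
    germline_confirmed: bool


def _place_svs(
    rng: np.random.Generator,
    seq: str,
    kinds: Sequence[str],
    genome_length: int,
    clearance: int = 800,
) -> List[Tuple[str, int, int]]:
    """Choose non-overlapping, unambiguous SV intervals with probe room."""
    placed: List[Tuple[str, int, int]] = []
    blocked: List[Tuple[int, int]] = []
    for kind in kinds:
        size_lo, size_hi = (600, 2500) if kind == "DEL" else (1200, 2600)
        for _ in range(500):
            size = int(rng.integers(size_lo, size_hi))
            start = int(rng.integers(1000, genome_length - 1000 - size))
            end = start + size
            if any(start - clearance < be and end + clearance > bs for bs, be in blocked):
                continue
            if junction_is_ambiguous(seq, kind, start, end):
                continue
            placed.append((kind, start, end))
            blocked.append((start, end))
            break
        else:
            raise RuntimeError("could not place SV fixture without conflicts")
    return placed


def sv_experiment(
    seed: int,
    genome_length: int = 100_000,
    n_del: int = 5,
    n_inv: int = 2,
    n_germline: int = 1,
    cellularity: float = 0.40,
    n_fragments: int = 300_000,
    read1_len: int = 350,
) -> SvExperiment:
    """Implant deletions/inversions, capture, assemble and validate.

    The tumor sample mixes tumor-cell genome at the given cellularity
    with normal genome; the matched normal carries only the germline
    control variant.  Read 1 is 350 b so reads span junctions sitting
    150-300 b from their flanking probes.  Junction coordinates are
    placed microhomology-free so exact recovery is well defined.
    """
    rng = np.random.default_rng([seed, 31])
    genome, _ = simulate_genome(genome_length, rng)
    seq = genome["chr1"].seq

    kinds = ["DEL"] * n_del + ["INV"] * n_inv + ["DEL"] * n_germline
    placed = _place_svs(rng, seq, kinds, genome_length)
    somatic_placed = placed[: n_del + n_inv]
    germline_placed = placed[n_del + n_inv :]

    def to_variant(kind: str, start: int, end: int):
        return Deletion("chr1", start, end) if kind == "DEL" else Inversion("chr1", start, end)

    tumor_vars = [to_variant(*p) for p in placed]
    normal_vars = [to_variant(*p) for p in germline_placed]
    derived_tumor = implant_variants(genome, tumor_vars)
    derived_normal = implant_variants(genome, normal_vars)
    truth_somatic = [
        Junction("chr1", s, "chr1", e, k) for k, s, e in somatic_placed
    ]
    truth_germline = [
        Junction("chr1", s, "chr1", e, k) for k, s, e in germline_placed
    ]

    track = classify_positions(genome, 20, 1)
    probes: List[PrimerProbe] = []
    probe_to_locus: Dict[str, str] = {}
    expected_chrom: Dict[str, str] = {}
    for i, (kind, s, e) in enumerate(placed):
        locus = f"sv{i}_{kind.lower()}"
        target = BreakpointTarget("chr1", s, "chr1", e, kind, label=locus)
        res = design_for_breakpoint(target, genome, track)
        for p in res.probes:
            probe_to_locus[p.probe_id] = locus
        probes.extend(res.probes)
        expected_chrom[locus] = "chr1"
    finalize_catalog(probes)

    config = SimConfig(n_fragments=n_fragments, read1_len=read1_len)
    sim_tumor = simulate_capture(
        [
            SourceGenome("tumor_cells", derived_tumor.genome, cellularity,
                         derived_tumor.lift),
            SourceGenome("stromal_cells", derived_normal.genome, 1.0 - cellularity,
                         derived_normal.lift),
        ],
        probes, config, np.random.default_rng([seed, 32]), sample="tumor",
    )
    sim_normal = simulate_capture(
        [SourceGenome("normal_cells", derived_normal.genome, 1.0, derived_normal.lift)],
        probes, config, np.random.default_rng([seed, 33]), sample="normal",
    )

    assigner = ProbeAssigner(probes)
    assigned = []
    for sim in (sim_tumor, sim_normal):
        for r in sim.reads:
            pid = assigner.assign(r.read2)
            if pid != UNASSIGNED:
                assigned.append((sim.sample, r.read_id, pid, r.read1, r.qual1))
    groups = build_locus_groups(assigned, probe_to_locus)
    alignments = {"tumor": sim_tumor.alignments(), "normal": sim_normal.alignments()}
    resolutions = resolve_breakpoints(
        groups, alignments, genome,
        tumor_samples=["tumor"], normal_samples=["normal"],
        expected_chrom=expected_chrom,
    )
    calls = resolutions_to_frame(resolutions)

    somatic_truth_keys = {j.key() for j in truth_somatic}
    germline_truth_keys = {j.key() for j in truth_germline}
    recovered: Set[Tuple] = set()
    somatic_in_normal = 0
    germline_in_tumor: Set[Tuple] = set()
    germline_in_normal: Set[Tuple] = set()
    for res in resolutions:
        for junction, holders, somatic in res.junctions:
            key = junction.key()
            if key in somatic_truth_keys and somatic and "tumor" in holders:
                recovered.add(key)
            if "normal" in holders and key not in germline_truth_keys:
                somatic_in_normal += 1
            if key in germline_truth_keys:
                if "tumor" in holders:
                    germline_in_tumor.add(key)
                if "normal" in holders:
                    germline_in_normal.add(key)
    germline_ok = (
        germline_in_tumor == germline_truth_keys
        and germline_in_normal == germline_truth_keys
    )
    return SvExperiment(
        reference=genome,
        truth_somatic=truth_somatic,
        truth_germline=truth_germline,
        probes=probes,
        sim_tumor=sim_tumor,
        sim_normal=sim_normal,
        resolutions=resolutions,
        calls=calls,
        recovered_somatic=recovered,
        missed_somatic=somatic_truth_keys - recovered,
        somatic_calls_in_normal=somatic_in_normal,
        germline_confirmed=germline_ok,
    )
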