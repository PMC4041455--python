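"""Primer-probe placement for exon, locus, SNP and breakpoint targets.

A primer probe is a 101-mer oligo whose 5' 40 bases match the genome at
a 40-base anchor; immobilised on the flow cell it captures complementary
library strands and primes polymerase extension into the target.
Placement enforces the design gates used for flow-cell capture panels:

* GC content of the 40-mer between 30% and 65%;
* the extension-proximal 20-mer unique in the genome with a Hamming
  margin (no second site within ``uniqueness_margin`` substitutions);
* no known SNP under the extension-proximal 10 bases;
* no highly repetitive sequence immediately on the extension side;
* probes on both strands, flanking short targets within 100-200 bases
  and tiled roughly every 200 bases per strand across long targets.

Orientation convention: a "+" probe's 40-mer equals the forward
reference at its anchor and extension proceeds toward increasing
coordinates; a "-" probe's 40-mer is the reverse complement and
extension proceeds toward decreasing coordinates.  The "terminal"
20-mer/10-mer of the gate rules is always the extension-proximal end of
the synthesized 40-mer.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import pandas as pd
import yaml

from .genome import Genome, GenomeSequence, as_genome, reverse_complement
from .kmer import KmerTrack, MapabilityCode

PROBE_LEN = 40
TERMINAL_KMER_LEN = 20
OLIGO_LEN = 101

# Rule codes returned by candidate_passes_filters
GC_RANGE = "GC_RANGE"
KMER_NOT_UNIQUE = "KMER_NOT_UNIQUE"
SNP_IN_TERMINAL_10 = "SNP_IN_TERMINAL_10"
REPEAT_ADJACENT = "REPEAT_ADJACENT"
CONTAINS_N = "CONTAINS_N"


class TargetClass:
    EXON = "EXON"
    LOCUS = "LOCUS"
    SNP = "SNP"
    BREAKPOINT = "BREAKPOINT"


@dataclass(frozen=True)
class TargetRegion:
    chrom: str
    start: int
    end: int
    target_class: str = TargetClass.EXON
    label: str = ""

    def __post_init__(self):
        if self.target_class == TargetClass.SNP:
            if self.end != self.start + 1:
                raise ValueError("SNP targets must satisfy end == start + 1")
        elif self.start >= self.end:
            raise ValueError("interval targets must satisfy start < end")


@dataclass
class PrimerProbe:
    """A designed capture oligo anchored at a 40-base genomic footprint."""

    probe_id: str
    chrom: str
    anchor_start: int
    anchor_end: int
    strand: str
    target_seq_40: str
    gc_fraction: float
    parent_target: str = ""
    oligo_101: Optional[str] = None

    def __post_init__(self):
        if self.anchor_end - self.anchor_start != PROBE_LEN:
            raise ValueError("probe anchor must span exactly 40 bases")
        if len(self.target_seq_40) != PROBE_LEN:
            raise ValueError("target_seq_40 must be 40 bases")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.oligo_101 is not None and len(self.oligo_101) != OLIGO_LEN:
            raise ValueError("oligo_101 must be 101 bases")

    @property
    def extension_end(self) -> int:
        """Genomic coordinate of the extension-proximal anchor boundary."""
        return self.anchor_end if self.strand == "+" else self.anchor_start

    def terminal_kmer_track_pos(self) -> int:
        """Track position of the extension-proximal 20-mer window."""
        return (
            self.anchor_end - TERMINAL_KMER_LEN
            if self.strand == "+"
            else self.anchor_start
        )

    def terminal10_interval(self) -> Tuple[int, int]:
        if self.strand == "+":
            return self.anchor_end - 10, self.anchor_end
        return self.anchor_start, self.anchor_start + 10


@dataclass(frozen=True)
class DesignParams:
    gc_min: float = 0.30
    gc_max: float = 0.65
    tile_spacing: int = 200
    flank_window: Tuple[int, int] = (100, 200)
    snp_exclusion_len: int = 10
    uniqueness_margin: int = 1
    breakpoint_probe_distance: Tuple[int, int] = (150, 300)
    probes_per_breakpoint: int = 4
    # spacing tolerance for tiled placements ("approximately every 200 b")
    tile_tolerance: int = 60
    # extension-side exclusion distance for repeat-adjacent candidates
    repeat_adjacent_len: int = 20

    def __post_init__(self):
        if not self.gc_min < self.gc_max:
            raise ValueError("gc_min must be < gc_max")
        for v in (
            self.tile_spacing,
            *self.flank_window,
            self.snp_exclusion_len,
            *self.breakpoint_probe_distance,
            self.tile_tolerance,
            self.repeat_adjacent_len,
        ):
            if v <= 0:
                raise ValueError("all distances must be positive")


@dataclass(frozen=True)
class DesignGap:
    """A required placement window in which no candidate passed the gates."""

    parent_target: str
    chrom: str
    strand: str
    window_start: int
    window_end: int
    nominal: int
    reason: str


@dataclass
class DesignResult:
    probes: List[PrimerProbe] = field(default_factory=list)
    gaps: List[DesignGap] = field(default_factory=list)

    def extend(self, other: "DesignResult") -> None:
        self.probes.extend(other.probes)
        self.gaps.extend(other.gaps)


@dataclass(frozen=True)
class FilterDecision:
    passed: bool
    failures: Tuple[str, ...] = ()


def gc_content(seq: str) -> float:
    """Fraction of G+C bases; rejects empty or non-ACGT input."""
    if not seq:
        raise ValueError("empty sequence")
    counts = Counter(seq)
    if set(counts) - set("ACGT"):
        raise ValueError("gc_content requires an ACGT-only sequence")
    return (counts["G"] + counts["C"]) / len(seq)


def normalize_snps(
    snps: Union[None, Iterable[Tuple[str, int]], Mapping[str, Iterable[int]]]
) -> Dict[str, Set[int]]:
    """Normalise SNP inputs to a chrom -> {position} mapping."""
    out: Dict[str, Set[int]] = {}
    if snps is None:
        return out
    if isinstance(snps, Mapping):
        return {chrom: set(pos) for chrom, pos in snps.items()}
    for chrom, pos in snps:
        out.setdefault(chrom, set()).add(int(pos))
    return out


def read_snp_positions(path: Union[str, Path]) -> Dict[str, Set[int]]:
    """Read SNP positions from VCF (genotypes ignored) or 2+ column BED.

    Multi-allelic VCF records count as a single excluded position.  BED
    input is taken as 0-based starts; VCF POS is converted from 1-based.
    """
    out: Dict[str, Set[int]] = {}
    path = Path(path)
    is_vcf = path.suffix.lower() == ".vcf" or str(path).lower().endswith(".vcf.gz")
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom = fields[0]
            pos = int(fields[1]) - 1 if is_vcf else int(fields[1])
            out.setdefault(chrom, set()).add(pos)
    return out


def make_candidate(
    genome: Genome,
    chrom: str,
    anchor_start: int,
    strand: str,
    parent_target: str = "",
) -> PrimerProbe:
    """Construct a candidate probe from its anchor; no gates are applied."""
    seq = genome[chrom].seq
    if anchor_start < 0 or anchor_start + PROBE_LEN > len(seq):
        raise ValueError("anchor outside genome")
    window = seq[anchor_start : anchor_start + PROBE_LEN]
    target = window if strand == "+" else reverse_complement(window)
    gc = (window.count("G") + window.count("C")) / PROBE_LEN
    probe_id = f"{parent_target or 'probe'}|{chrom}:{anchor_start}{strand}"
    return PrimerProbe(
        probe_id=probe_id,
        chrom=chrom,
        anchor_start=anchor_start,
        anchor_end=anchor_start + PROBE_LEN,
        strand=strand,
        target_seq_40=target,
        gc_fraction=gc,
        parent_target=parent_target,
    )


def candidate_passes_filters(
    candidate: PrimerProbe,
    track: KmerTrack,
    snps: Union[None, Iterable[Tuple[str, int]], Mapping[str, Iterable[int]]],
    params: DesignParams = DesignParams(),
) -> FilterDecision:
    """Apply all placement gates; returns the complete set of violations."""
    failures: List[str] = []
    snp_map = normalize_snps(snps)

    if "N" in candidate.target_seq_40:
        failures.append(CONTAINS_N)
    if not (params.gc_min <= candidate.gc_fraction <= params.gc_max):
        failures.append(GC_RANGE)

    arr = track.track(candidate.chrom)
    kpos = candidate.terminal_kmer_track_pos()
    if not (0 <= kpos < len(arr)) or arr[kpos] != MapabilityCode.UNIQUE_D1:
        failures.append(KMER_NOT_UNIQUE)

    t10_start, t10_end = candidate.terminal10_interval()
    chrom_snps = snp_map.get(candidate.chrom, set())
    if any(t10_start <= p < t10_end for p in chrom_snps):
        failures.append(SNP_IN_TERMINAL_10)

    # repeat-adjacency: any REPETITIVE k-mer window overlapping the
    # repeat_adjacent_len bases immediately on the extension side
    d = params.repeat_adjacent_len
    if candidate.strand == "+":
        region_lo, region_hi = candidate.anchor_end, candidate.anchor_end + d
    else:
        region_lo, region_hi = candidate.anchor_start - d, candidate.anchor_start
    lo = max(0, region_lo - track.k + 1)
    hi = min(len(arr), region_hi)
    if hi > lo and (arr[lo:hi] == MapabilityCode.REPETITIVE).any():
        failures.append(REPEAT_ADJACENT)

    return FilterDecision(passed=not failures, failures=tuple(sorted(failures)))


@dataclass(frozen=True)
class PlacementWindow:
    """A range of admissible anchor starts with a preferred position."""

    chrom: str
    strand: str
    lo: int  # inclusive anchor_start bound
    hi: int  # inclusive anchor_start bound
    nominal: int


def _clip_window(w: PlacementWindow, seq_len: int) -> Optional[PlacementWindow]:
    lo = max(0, w.lo)
    hi = min(seq_len - PROBE_LEN, w.hi)
    if hi < lo:
        return None
    return replace(w, lo=lo, hi=hi)


def _search_window(
    window: PlacementWindow,
    genome: Genome,
    track: KmerTrack,
    snps,
    params: DesignParams,
    parent: str,
) -> Tuple[Optional[PrimerProbe], Optional[DesignGap]]:
    """Pick the passing candidate closest to the nominal anchor.

    Ties break toward the smaller coordinate so catalogs are
    deterministic for identical inputs.
    """
    seq_len = len(genome[window.chrom].seq)
    clipped = _clip_window(window, seq_len)
    if clipped is None:
        gap = DesignGap(
            parent, window.chrom, window.strand, window.lo, window.hi + 1,
            window.nominal, "window outside genome",
        )
        return None, gap
    fail_tally: Counter = Counter()
    anchors = sorted(
        range(clipped.lo, clipped.hi + 1),
        key=lambda a: (abs(a - clipped.nominal), a),
    )
    snp_map = normalize_snps(snps)
    for a in anchors:
        cand = make_candidate(genome, clipped.chrom, a, clipped.strand, parent)
        decision = candidate_passes_filters(cand, track, snp_map, params)
        if decision.passed:
            return cand, None
        fail_tally.update(decision.failures)
    reason = "no passing candidate; failures: " + ", ".join(
        f"{k}={v}" for k, v in sorted(fail_tally.items())
    )
    gap = DesignGap(
        parent, clipped.chrom, clipped.strand, clipped.lo, clipped.hi + 1,
        clipped.nominal, reason,
    )
    return None, gap


def interval_windows(
    target: TargetRegion, params: DesignParams = DesignParams()
) -> List[PlacementWindow]:
    """Placement windows for an interval target.

    One flanking window per strand whose extension end falls 100-200 b
    outside the target boundary, plus tiled windows roughly every
    ``tile_spacing`` per strand for targets longer than the spacing.
    """
    s, e = target.start, target.end
    fmin, fmax = params.flank_window
    tol = params.tile_tolerance
    windows: List[PlacementWindow] = []

    # "+" strand: extension end at s - fmax .. s - fmin, then tiles inward
    plus_ends = [((s - fmax) - PROBE_LEN, (s - fmin) - PROBE_LEN, None)]
    if e - s > params.tile_spacing:
        ext = s - fmin + params.tile_spacing
        while ext <= e:
            a = ext - PROBE_LEN
            plus_ends.append((a - tol, a + tol, a))
            ext += params.tile_spacing
    for lo, hi, nom in plus_ends:
        nominal = nom if nom is not None else (lo + hi) // 2
        windows.append(PlacementWindow(target.chrom, "+", lo, hi, nominal))

    # "-" strand mirrored: extension end (anchor_start) at e + fmin .. e + fmax
    minus_starts = [(e + fmin, e + fmax, None)]
    if e - s > params.tile_spacing:
        ext = e + fmin - params.tile_spacing
        while ext >= s:
            minus_starts.append((ext - tol, ext + tol, ext))
            ext -= params.tile_spacing
    for lo, hi, nom in minus_starts:
        nominal = nom if nom is not None else (lo + hi) // 2
        windows.append(PlacementWindow(target.chrom, "-", lo, hi, nominal))
    return windows


def design_for_interval(
    target: TargetRegion,
    genome: Union[Genome, GenomeSequence, Mapping[str, str]],
    track: KmerTrack,
    snps=None,
    params: DesignParams = DesignParams(),
) -> DesignResult:
    """Place probes on both strands flanking and tiling an interval target."""
    g = as_genome(genome)
    result = DesignResult()
    seen: Set[Tuple[str, int, str]] = set()
    label = target.label or f"{target.chrom}:{target.start}-{target.end}"
    for window in interval_windows(target, params):
        probe, gap = _search_window(window, g, track, snps, params, label)
        if probe is not None:
            key = (probe.chrom, probe.anchor_start, probe.strand)
            if key not in seen:
                seen.add(key)
                result.probes.append(probe)
        elif gap is not None:
            result.gaps.append(gap)
    return result


def design_for_snp(
    position: Tuple[str, int],
    genome: Union[Genome, GenomeSequence, Mapping[str, str]],
    track: KmerTrack,
    snps=None,
    params: DesignParams = DesignParams(),
) -> DesignResult:
    """One probe per strand whose extension reads across a SNP position.

    Anchors sit 100-200 b (extension-end distance) from the SNP, so the
    targeted SNP can never fall inside a probe's terminal 10 bases.
    """
    chrom, pos = position
    g = as_genome(genome)
    fmin, fmax = params.flank_window
    mid_plus = (pos - fmax + pos - fmin) // 2 - PROBE_LEN
    mid_minus = (pos + fmin + pos + fmax) // 2
    windows = [
        PlacementWindow(chrom, "+", (pos - fmax) - PROBE_LEN, (pos - fmin) - PROBE_LEN, mid_plus),
        PlacementWindow(chrom, "-", pos + fmin, pos + fmax, mid_minus),
    ]
    label = f"SNP|{chrom}:{pos}"
    result = DesignResult()
    for window in windows:
        probe, gap = _search_window(window, g, track, snps, params, label)
        if probe is not None:
            result.probes.append(probe)
        elif gap is not None:
            result.gaps.append(gap)
    return result


@dataclass(frozen=True)
class BreakpointTarget:
    """A putative SV junction to flank with probes (coordinates on the
    reference; ``chrom2``/``pos2`` may name a second chromosome)."""

    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    sv_type: str = "DEL"
    label: str = ""


def design_for_breakpoint(
    candidate_sv: BreakpointTarget,
    genome: Union[Genome, GenomeSequence, Mapping[str, str]],
    track: KmerTrack,
    snps=None,
    params: DesignParams = DesignParams(),
) -> DesignResult:
    """Probes flanking a putative junction, extension oriented toward it.

    Half the probes sit on the "+" strand 150-300 b upstream of the
    first coordinate, half on the "-" strand 150-300 b downstream of the
    second, so reads from both sides cross the junction.  The distance
    range is split into one sub-window per probe slot.
    """
    g = as_genome(genome)
    dmin, dmax = params.breakpoint_probe_distance
    n_side = max(1, params.probes_per_breakpoint // 2)
    step = (dmax - dmin) / n_side
    label = candidate_sv.label or (
        f"BP|{candidate_sv.chrom1}:{candidate_sv.pos1}-"
        f"{candidate_sv.chrom2}:{candidate_sv.pos2}"
    )
    windows: List[PlacementWindow] = []
    for i in range(n_side):
        d0, d1 = int(dmin + i * step), int(dmin + (i + 1) * step)
        # "+" probes upstream of pos1: extension end at pos1 - d
        lo = candidate_sv.pos1 - d1 - PROBE_LEN
        hi = candidate_sv.pos1 - d0 - PROBE_LEN
        windows.append(
            PlacementWindow(candidate_sv.chrom1, "+", lo, hi, (lo + hi) // 2)
        )
        # "-" probes downstream of pos2: extension end (anchor_start) at pos2 + d
        lo2, hi2 = candidate_sv.pos2 + d0, candidate_sv.pos2 + d1
        windows.append(
            PlacementWindow(candidate_sv.chrom2, "-", lo2, hi2, (lo2 + hi2) // 2)
        )
    result = DesignResult()
    for window in windows:
        probe, gap = _search_window(window, g, track, snps, params, label)
        if probe is not None:
            result.probes.append(probe)
        elif gap is not None:
            result.gaps.append(gap)
    return result


def load_universal_segments(path: Optional[Union[str, Path]] = None) -> Dict[str, str]:
    """Load the universal mid/P7 segments (defaults ship with the package)."""
    if path is None:
        ref = resources.files("osseq").joinpath("data/universal_segments.yaml")
        data = yaml.safe_load(ref.read_text())
    else:
        data = yaml.safe_load(Path(path).read_text())
    mid, p7 = data["universal_mid"].upper(), data["p7_complement"].upper()
    if len(mid) + len(p7) != OLIGO_LEN - PROBE_LEN:
        raise ValueError("universal segments must sum to 61 bases")
    return {"universal_mid": mid, "p7_complement": p7}


def assemble_oligo(probe: PrimerProbe, universal_mid: str, p7_complement: str) -> str:
    """Concatenate 40-mer + universal mid + P7 complement into the 101-mer."""
    if len(probe.target_seq_40) != PROBE_LEN:
        raise ValueError("target_seq_40 must be 40 bases")
    if len(universal_mid) + len(p7_complement) != OLIGO_LEN - PROBE_LEN:
        raise ValueError("universal segments must sum to 61 bases")
    oligo = probe.target_seq_40 + universal_mid + p7_complement
    probe.oligo_101 = oligo
    return oligo


def finalize_catalog(
    probes: Iterable[PrimerProbe], segments: Optional[Dict[str, str]] = None
) -> List[PrimerProbe]:
    """Assemble the full 101-mer for every probe in a catalog."""
    segs = segments or load_universal_segments()
    out = list(probes)
    for p in out:
        assemble_oligo(p, segs["universal_mid"], segs["p7_complement"])
    return out


def probe_density(
    probes: Sequence[PrimerProbe], targets: Sequence[TargetRegion]
) -> float:
    """Probes per kilobase of targeted sequence."""
    if not targets:
        raise ValueError("targets must be non-empty")
    total_kb = sum(t.end - t.start for t in targets) / 1000.0
    if total_kb <= 0:
        raise ValueError("targets span zero bases")
    return len(probes) / total_kb


# ---------------------------------------------------------------------------
# catalog / report I/O

CATALOG_COLUMNS = [
    "probe_id", "chrom", "anchor_start", "anchor_end", "strand",
    "target_seq_40", "gc", "oligo_101", "parent_target",
]


def catalog_to_frame(probes: Iterable[PrimerProbe]) -> pd.DataFrame:
    rows = [
        {
            "probe_id": p.probe_id,
            "chrom": p.chrom,
            "anchor_start": p.anchor_start,
            "anchor_end": p.anchor_end,
            "strand": p.strand,
            "target_seq_40": p.target_seq_40,
            "gc": round(p.gc_fraction, 4),
            "oligo_101": p.oligo_101 or "",
            "parent_target": p.parent_target,
        }
        for p in probes
    ]
    return pd.DataFrame(rows, columns=CATALOG_COLUMNS)


def write_catalog(probes: Iterable[PrimerProbe], path: Union[str, Path]) -> None:
    catalog_to_frame(probes).to_csv(path, sep="\t", index=False)


def read_catalog(path: Union[str, Path]) -> List[PrimerProbe]:
    df = pd.read_csv(path, sep="\t", dtype={"oligo_101": str}, keep_default_na=False)
    probes = []
    for row in df.itertuples(index=False):
        probes.append(
            PrimerProbe(
                probe_id=row.probe_id,
                chrom=str(row.chrom),
                anchor_start=int(row.anchor_start),
                anchor_end=int(row.anchor_end),
                strand=row.strand,
                target_seq_40=row.target_seq_40,
                gc_fraction=float(row.gc),
                parent_target=str(row.parent_target),
                oligo_101=row.oligo_101 or None,
            )
        )
    return probes


def write_expected_capture_bed(
    probes: Iterable[PrimerProbe], path: Union[str, Path], flank: int = 50
) -> None:
    """Anchor +/- flank intervals (merged) where capture reads are expected."""
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for p in probes:
        by_chrom.setdefault(p.chrom, []).append(
            (max(0, p.anchor_start - flank), p.anchor_end + flank)
        )
    with open(path, "w") as fh:
        for chrom in sorted(by_chrom):
            merged: List[List[int]] = []
            for s, e in sorted(by_chrom[chrom]):
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            for s, e in merged:
                fh.write(f"{chrom}\t{s}\t{e}\n")


def write_gap_report(gaps: Iterable[DesignGap], path: Union[str, Path]) -> None:
    rows = [
        {
            "parent_target": gapr.parent_target,
            "chrom": gapr.chrom,
            "strand": gapr.strand,
            "window_start": gapr.window_start,
            "window_end": gapr.window_end,
            "nominal": gapr.nominal,
            "reason": gapr.reason,
        }
        for gapr in gaps
    ]
    pd.DataFrame(
        rows,
        columns=[
            "parent_target", "chrom", "strand", "window_start",
            "window_end", "nominal", "reason",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_targets_bed(path: Union[str, Path]) -> List[TargetRegion]:
    """Read targets from BED (chrom, start, end[, label[, class]])."""
    targets = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            label = fields[3] if len(fields) > 3 else ""
            tclass = fields[4] if len(fields) > 4 else TargetClass.EXON
            targets.append(TargetRegion(chrom, start, end, tclass, label))
    return targets
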