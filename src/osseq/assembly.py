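"""Structural-variant breakpoint resolution by probe-grouped local assembly.

Reads captured by the probes flanking one candidate rearrangement are
aggregated into a locus group (via their Read-2 probe index), purged of
reference-matching, low-quality and adapter-bearing reads, and the
remainder assembled with a small de Bruijn assembler.  Contigs are then
split-aligned against the reference: a validated junction is a contig
whose prefix and suffix each match the reference exactly at two
different loci, with a discontinuity between them, and which has no
counterpart in the matched normal sample.

Also included are the upstream filters applied to whole-genome SV
candidate calls before an assay is designed against them: per-sample
support thresholds, germline subtraction, sex-plausibility and
repeat-anchor exclusion.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import pandas as pd

from .genome import Genome, as_genome, reverse_complement
from .qc import AlignedRead, mean_phred

PRIMER2 = "AGATCGGAAGAGCGGT"
PRIMER2_RC = reverse_complement(PRIMER2)  # ACCGCTCTTCCGATCT

# contig rejection reasons
FULLY_REFERENCE = "FULLY_REFERENCE"
WRONG_CHROM = "WRONG_CHROM"
GERMLINE = "GERMLINE"
NO_SPLIT = "NO_SPLIT"


@dataclass(frozen=True)
class SvCandidate:
    """A whole-genome SV candidate consumed from an external caller."""

    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    sv_type: str
    support: Mapping[str, int]  # sample name -> supporting read count
    anchor_len: int = 20

    def chroms(self) -> Tuple[str, str]:
        return self.chrom1, self.chrom2


def _overlaps_mask(
    mask: Optional[Mapping[str, Sequence[Tuple[int, int]]]],
    chrom: str,
    start: int,
    end: int,
) -> bool:
    if not mask:
        return False
    for s, e in mask.get(chrom, ()):
        if start < e and end > s:
            return True
    return False


def filter_sv_candidates(
    candidates: Iterable[SvCandidate],
    sex: str,
    tumor_samples: Sequence[str],
    normal_samples: Sequence[str] = (),
    min_reads_single: int = 20,
    min_reads_shared: int = 10,
    repeat_mask: Optional[Mapping[str, Sequence[Tuple[int, int]]]] = None,
) -> List[SvCandidate]:
    """Keep candidates passing support, germline, sex and repeat filters.

    A candidate survives iff it has >= ``min_reads_single`` supporting
    reads in one tumor sample or >= ``min_reads_shared`` in at least two
    tumor samples, no support in any normal sample, chromosomes
    plausible for the stated sex (no Y involvement in a female), anchor
    length of at least 20 bases, and neither anchor inside the repeat
    mask.
    """
    kept: List[SvCandidate] = []
    y_names = {"Y", "chrY"}
    for cand in candidates:
        tumor_support = [cand.support.get(s, 0) for s in tumor_samples]
        strong = any(v >= min_reads_single for v in tumor_support)
        shared = sum(v >= min_reads_shared for v in tumor_support) >= 2
        if not (strong or shared):
            continue
        if any(cand.support.get(s, 0) > 0 for s in normal_samples):
            continue
        if sex.lower() == "female" and (set(cand.chroms()) & y_names):
            continue
        if cand.anchor_len < 20:
            continue
        a = cand.anchor_len
        if _overlaps_mask(repeat_mask, cand.chrom1, cand.pos1 - a, cand.pos1 + a):
            continue
        if _overlaps_mask(repeat_mask, cand.chrom2, cand.pos2 - a, cand.pos2 + a):
            continue
        kept.append(cand)
    return kept


@dataclass(frozen=True)
class AssemblyRead:
    read_id: str
    seq: str
    qual: str


@dataclass
class LocusGroup:
    """Reads aggregated by the probes flanking one candidate breakpoint,
    kept separate per sample."""

    locus_id: str
    probe_ids: Tuple[str, ...]
    reads_by_sample: Dict[str, List[AssemblyRead]] = field(default_factory=dict)

    def add(self, sample: str, read: AssemblyRead) -> None:
        self.reads_by_sample.setdefault(sample, []).append(read)

    def n_reads(self, sample: str) -> int:
        return len(self.reads_by_sample.get(sample, []))


def build_locus_groups(
    assigned_reads: Iterable[Tuple[str, str, str, str, str]],
    probe_to_locus: Mapping[str, str],
) -> Dict[str, LocusGroup]:
    """Partition reads into locus groups by their assigned probe.

    ``assigned_reads`` yields (sample, read_id, probe_id, read1_seq,
    read1_qual); reads whose probe is unassigned or maps to no locus are
    discarded.  Tumor and normal reads stay in separate per-sample bins.
    """
    locus_probes: Dict[str, List[str]] = {}
    for pid, locus in probe_to_locus.items():
        locus_probes.setdefault(locus, []).append(pid)
    groups: Dict[str, LocusGroup] = {
        locus: LocusGroup(locus, tuple(sorted(pids)))
        for locus, pids in locus_probes.items()
    }
    for sample, read_id, probe_id, seq, qual in assigned_reads:
        locus = probe_to_locus.get(probe_id)
        if locus is None:
            continue
        groups[locus].add(sample, AssemblyRead(read_id, seq, qual))
    return groups


def filter_reads_for_assembly(
    reads: Iterable[AssemblyRead],
    alignments: Mapping[str, AlignedRead],
    min_mean_qual: float = 25,
    primer2: str = PRIMER2,
) -> List[AssemblyRead]:
    """Retain breakpoint-informative reads for local assembly.

    Keeps reads whose mean Phred quality exceeds ``min_mean_qual``, that
    did not fully align to the reference (reference-matching reads carry
    no junction), and that do not contain the sequencing primer-2
    sequence or its reverse complement (which would otherwise seed
    adapter contigs).  Reads with no alignment record are treated as
    unaligned and kept.
    """
    p2_rc = reverse_complement(primer2)
    out: List[AssemblyRead] = []
    for read in reads:
        if mean_phred(read.qual) <= min_mean_qual:
            continue
        aln = alignments.get(read.read_id)
        if aln is not None and aln.fully_aligned:
            continue
        if primer2 in read.seq or p2_rc in read.seq:
            continue
        out.append(read)
    return out


@dataclass
class Contig:
    sequence: str
    length: int
    mean_coverage: float
    locus_id: str = ""
    sample: str = ""


def assemble_locus(
    reads: Sequence[Union[AssemblyRead, str]],
    k: int = 19,
    min_contig_len: int = 50,
    min_coverage: float = 4,
    kmer_count_floor: Optional[int] = None,
) -> List[Contig]:
    """Local de Bruijn assembly of one locus group.

    k-mers are counted on both strands; k-mers seen fewer than
    ``kmer_count_floor`` times (default: ``min_coverage``, mirroring an
    abundance-based graph cleaning step) are dropped before the graph is
    built, which removes sequencing-error branches.  Contigs are the
    maximal non-branching paths of the remaining graph; each contig is
    reported once in its lexicographically smaller orientation, and
    contigs shorter than ``min_contig_len`` or with mean k-mer count
    below ``min_coverage`` are suppressed.
    """
    floor = int(min_coverage) if kmer_count_floor is None else kmer_count_floor
    counts: Counter = Counter()
    for read in reads:
        seq = read.seq if isinstance(read, AssemblyRead) else read
        if len(seq) < k:
            continue
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if "N" in km:
                continue
            counts[km] += 1
            counts[reverse_complement(km)] += 1
    kmers = {km for km, c in counts.items() if c >= floor}
    if not kmers:
        return []

    out_edges: Dict[str, List[str]] = {}
    in_deg: Counter = Counter()
    out_deg: Counter = Counter()
    for km in kmers:
        u, v = km[:-1], km[1:]
        out_edges.setdefault(u, []).append(km)
        out_deg[u] += 1
        in_deg[v] += 1

    def is_junction(node: str) -> bool:
        return in_deg[node] != 1 or out_deg[node] != 1

    for node in out_edges.values():
        node.sort()  # deterministic walk order

    visited: Set[str] = set()
    raw: List[Tuple[str, float]] = []

    def walk(start_km: str) -> None:
        path = [start_km]
        visited.add(start_km)
        node = start_km[1:]
        while not is_junction(node):
            nxt = out_edges.get(node, [None])[0]
            if nxt is None or nxt in visited:
                break
            path.append(nxt)
            visited.add(nxt)
            node = nxt[1:]
        seq = path[0] + "".join(km[-1] for km in path[1:])
        cov = sum(counts[km] for km in path) / len(path)
        raw.append((seq, cov))

    for km in sorted(kmers):
        if km not in visited and is_junction(km[: k - 1]):
            walk(km)
    for km in sorted(kmers):  # isolated cycles
        if km not in visited:
            walk(km)

    contigs: Dict[str, Contig] = {}
    for seq, cov in raw:
        if len(seq) < min_contig_len or cov < min_coverage:
            continue
        canon = min(seq, reverse_complement(seq))
        if canon not in contigs:
            contigs[canon] = Contig(canon, len(canon), cov)
        else:
            contigs[canon].mean_coverage = max(contigs[canon].mean_coverage, cov)
    return [contigs[key] for key in sorted(contigs)]


@dataclass(frozen=True)
class Junction:
    """A validated junction: two reference coordinates fused by an SV."""

    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    sv_type: str = "DEL"

    def key(self) -> Tuple[str, int, str, int]:
        return (self.chrom1, self.pos1, self.chrom2, self.pos2)


@dataclass
class BreakpointCall:
    junction: Junction
    contig: Contig
    homology_len: int = 0
    somatic: Optional[bool] = None


@dataclass(frozen=True)
class ContigRejection:
    reason: str
    detail: str = ""


def _occurrences(seq: str, ref: Genome) -> List[Tuple[str, int, int, str]]:
    """All exact occurrences of ``seq`` in the reference, both strands."""
    hits: List[Tuple[str, int, int, str]] = []
    rc = reverse_complement(seq)
    for name, rec in ref.items():
        text = rec.seq
        for query, strand in ((seq, "+"), (rc, "-")):
            start = text.find(query)
            while start != -1:
                hits.append((name, start, start + len(query), strand))
                start = text.find(query, start + 1)
        if seq == rc and hits:
            # palindromic query: forward and reverse hits coincide
            hits = list(dict.fromkeys(hits))
    return hits


def _full_reference_match(seq: str, ref: Genome) -> bool:
    rc = reverse_complement(seq)
    return any(
        rec.seq.find(seq) != -1 or rec.seq.find(rc) != -1 for rec in ref.sequences()
    )


def _candidate_junctions(
    contig: str, ref: Genome, min_anchor: int
) -> Dict[Tuple, List[int]]:
    """Enumerate split representations contig = prefix . suffix.

    Both segments are matched exactly against either strand of the
    reference.  Returns junction -> list of split positions that
    produce it; junctions are normalised so pos1 <= pos2 on a shared
    chromosome.  The reference-contiguous split (prefix immediately
    followed by suffix) is excluded.
    """
    found: Dict[Tuple, List[int]] = {}
    n = len(contig)
    for t in range(min_anchor, n - min_anchor + 1):
        pref_hits = _occurrences(contig[:t], ref)
        if not pref_hits:
            continue
        suf_hits = _occurrences(contig[t:], ref)
        if not suf_hits:
            continue
        for pc, ps, pe, pstrand in pref_hits:
            for sc, ss, se, sstrand in suf_hits:
                if (
                    pc == sc
                    and pstrand == "+"
                    and sstrand == "+"
                    and ss == pe
                ):
                    continue  # contiguous reference, not a junction
                if pc == sc and pstrand == "-" and sstrand == "-" and se == ps:
                    continue
                # junction coordinate at the read-direction end of each segment
                pos1 = pe if pstrand == "+" else ps
                pos2 = ss if sstrand == "+" else se
                c1, c2 = pc, sc
                s1, s2 = pstrand, sstrand
                if (c1, pos1) > (c2, pos2):
                    c1, c2, pos1, pos2 = c2, c1, pos2, pos1
                    s1, s2 = _flip(s2), _flip(s1)
                sv_type = _infer_type(c1, c2, s1, s2)
                key = (c1, pos1, c2, pos2, sv_type)
                found.setdefault(key, []).append(t)
    return found


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _equivalence_key(key: Tuple) -> Tuple:
    """Group equivalent junction representations shifted by microhomology.

    Sliding a deletion-type split by one base moves pos1 and pos2
    together (constant pos2 - pos1); sliding an inversion-type split
    moves them in opposite directions (constant pos2 + pos1).
    """
    c1, p1, c2, p2, sv_type = key
    if c1 == c2 and sv_type == "DEL":
        return (c1, c2, sv_type, p2 - p1)
    if c1 == c2 and sv_type == "INV":
        return (c1, c2, sv_type, p2 + p1)
    return key


def _infer_type(c1: str, c2: str, s1: str, s2: str) -> str:
    if c1 != c2:
        return "TRA"
    if s1 == s2:
        return "DEL"
    return "INV"


def validate_contig(
    contig: Union[Contig, str],
    reference: Union[Genome, Mapping[str, str]],
    normal_contigs: Sequence[Union[Contig, str]] = (),
    expected_chrom: Optional[str] = None,
    min_anchor: int = 20,
) -> Union[BreakpointCall, ContigRejection]:
    """Split-align a contig against the reference and call its junction.

    The contig must decompose as prefix + suffix with each segment
    matching the reference exactly (either strand) at least
    ``min_anchor`` bases long, the two matches discontinuous.  When
    junction microhomology makes several splits valid, the
    representation with the smallest pos1 is reported and the homology
    length recorded.  Rejections: FULLY_REFERENCE (no junction),
    NO_SPLIT (no exact two-segment decomposition), WRONG_CHROM (a
    segment off the expected chromosome), GERMLINE (same junction found
    in a matched-normal contig).
    """
    ref = as_genome(reference)
    seq = contig.sequence if isinstance(contig, Contig) else contig
    if _full_reference_match(seq, ref):
        return ContigRejection(FULLY_REFERENCE)
    found = _candidate_junctions(seq, ref, min_anchor)
    if not found:
        return ContigRejection(NO_SPLIT)
    if expected_chrom is not None:
        on_chrom = {
            key: ts
            for key, ts in found.items()
            if key[0] == expected_chrom and key[2] == expected_chrom
        }
        if not on_chrom:
            return ContigRejection(WRONG_CHROM, detail=str(sorted(found)[0]))
        found = on_chrom
    groups: Dict[Tuple, List[Tuple]] = {}
    for key in found:
        groups.setdefault(_equivalence_key(key), []).append(key)
    best_keys = {
        min(keys, key=lambda item: (item[1], item[3], item[0], item[2], item[4])): keys
        for keys in groups.values()
    }
    key = min(best_keys, key=lambda item: (item[1], item[3], item[0], item[2], item[4]))
    homology = len(best_keys[key]) - 1
    junction = Junction(key[0], key[1], key[2], key[3], key[4])
    for nc in normal_contigs:
        nres = validate_contig(nc, ref, expected_chrom=None, min_anchor=min_anchor)
        if isinstance(nres, BreakpointCall) and nres.junction.key() == junction.key():
            return ContigRejection(GERMLINE, detail=str(junction.key()))
    call_contig = contig if isinstance(contig, Contig) else Contig(seq, len(seq), 0.0)
    return BreakpointCall(junction=junction, contig=call_contig, homology_len=homology)


@dataclass
class LocusResolution:
    locus_id: str
    non_aligning_reads: Dict[str, int]
    contig_by_sample: Dict[str, bool]
    junctions: List[Tuple[Junction, Tuple[str, ...], bool]]  # junction, samples, somatic


def resolve_breakpoints(
    groups: Mapping[str, LocusGroup],
    alignments_by_sample: Mapping[str, Mapping[str, AlignedRead]],
    reference: Union[Genome, Mapping[str, str]],
    tumor_samples: Sequence[str],
    normal_samples: Sequence[str],
    expected_chrom: Optional[Mapping[str, str]] = None,
    k: int = 19,
    min_contig_len: int = 50,
    min_coverage: float = 4,
    min_mean_qual: float = 25,
    min_anchor: int = 20,
) -> List[LocusResolution]:
    """Full per-locus pipeline: filter reads, assemble per sample,
    validate contigs, and flag junctions somatic when they appear in a
    tumor but in no normal sample."""
    ref = as_genome(reference)
    results: List[LocusResolution] = []
    samples = list(tumor_samples) + list(normal_samples)
    for locus_id in sorted(groups):
        group = groups[locus_id]
        reads_used: Dict[str, List[AssemblyRead]] = {}
        junctions_by_sample: Dict[str, Dict[Tuple, BreakpointCall]] = {}
        contig_flag: Dict[str, bool] = {}
        for sample in samples:
            filtered = filter_reads_for_assembly(
                group.reads_by_sample.get(sample, []),
                alignments_by_sample.get(sample, {}),
                min_mean_qual=min_mean_qual,
            )
            reads_used[sample] = filtered
            contigs = assemble_locus(
                filtered, k=k, min_contig_len=min_contig_len, min_coverage=min_coverage
            )
            calls: Dict[Tuple, BreakpointCall] = {}
            for contig in contigs:
                contig.locus_id = locus_id
                contig.sample = sample
                res = validate_contig(
                    contig,
                    ref,
                    expected_chrom=(expected_chrom or {}).get(locus_id),
                    min_anchor=min_anchor,
                )
                if isinstance(res, BreakpointCall):
                    calls[res.junction.key()] = res
            junctions_by_sample[sample] = calls
            contig_flag[sample] = bool(calls)
        all_keys = sorted(
            {key for calls in junctions_by_sample.values() for key in calls}
        )
        merged: List[Tuple[Junction, Tuple[str, ...], bool]] = []
        for key in all_keys:
            holders = tuple(
                s for s in samples if key in junctions_by_sample[s]
            )
            in_tumor = any(s in tumor_samples for s in holders)
            in_normal = any(s in normal_samples for s in holders)
            somatic = in_tumor and not in_normal
            example = next(
                junctions_by_sample[s][key] for s in holders
            )
            merged.append((example.junction, holders, somatic))
        results.append(
            LocusResolution(
                locus_id=locus_id,
                non_aligning_reads={s: len(reads_used[s]) for s in samples},
                contig_by_sample=contig_flag,
                junctions=merged,
            )
        )
    return results


def resolutions_to_frame(results: Sequence[LocusResolution]) -> pd.DataFrame:
    """Tabular calls: one row per (locus, junction), with per-sample
    non-aligning read counts and contig flags."""
    rows = []
    for res in results:
        base = {"locus": res.locus_id}
        for sample, n in res.non_aligning_reads.items():
            base[f"nonaligning_reads_{sample}"] = n
        for sample, flag in res.contig_by_sample.items():
            base[f"contig_{sample}"] = "yes" if flag else "-"
        if not res.junctions:
            rows.append({**base, "chrom": "", "breakpoint1": -1, "breakpoint2": -1,
                         "sv_type": "", "somatic": "", "samples": ""})
        for junction, holders, somatic in res.junctions:
            rows.append(
                {
                    **base,
                    "chrom": junction.chrom1
                    if junction.chrom1 == junction.chrom2
                    else f"{junction.chrom1}/{junction.chrom2}",
                    "breakpoint1": junction.pos1,
                    "breakpoint2": junction.pos2,
                    "sv_type": junction.sv_type,
                    "somatic": somatic,
                    "samples": ",".join(holders),
                }
            )
    return pd.DataFrame(rows)
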