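"""Capture QC: demultiplexing, Read-2 probe assignment, on-target
classification, yield/uniformity metrics, ROI coverage and a naive
allele-fraction caller.

In this assay the second read of each pair begins with the synthetic
40-mer of the probe that captured the fragment, so Read 2 is a perfect
per-read index of the originating probe.  All capture metrics are built
on that assignment: per-probe on-target yield, the capture rate
(fraction of probes with any on-target read) and 1-log uniformity (the
fraction of probes whose yield lies within a factor of ten of the
median probe yield).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import pysam

from .design import PrimerProbe
from .genome import Genome

UNASSIGNED = "UNASSIGNED"
TAG_LEN = 7

# off-target reasons
WRONG_CHROM = "WRONG_CHROM"
WRONG_ORIENTATION = "WRONG_ORIENTATION"
DISTANCE_EXCEEDED = "DISTANCE_EXCEEDED"


@dataclass
class ReadPair:
    read_id: str
    read1_seq: str
    read1_qual: str
    read2_seq: str
    read2_qual: str
    index_tag: Optional[str] = None

    def __post_init__(self):
        if len(self.read1_seq) != len(self.read1_qual):
            raise ValueError("read1 quality length mismatch")
        if len(self.read2_seq) != len(self.read2_qual):
            raise ValueError("read2 quality length mismatch")


@dataclass
class AlignedRead:
    """A consumed alignment record for Read 1 (alignment itself is external)."""

    read_id: str
    chrom: Optional[str]
    pos: int
    strand: str
    mapq: int
    aln_len: int
    fully_aligned: bool
    mapped: bool = True
    seq: str = ""
    qual: str = ""

    def __post_init__(self):
        if self.mapped and self.pos < 0:
            raise ValueError("mapped read with negative position")
        if self.mapq < 0:
            raise ValueError("negative mapping quality")

    @property
    def end(self) -> int:
        return self.pos + self.aln_len


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass
class DemuxResult:
    by_sample: Dict[str, List[ReadPair]]
    unassigned: List[ReadPair]

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.by_sample.values()) + len(self.unassigned)


def demultiplex(
    pairs: Iterable[ReadPair],
    sample_table: Mapping[str, str],
    max_mismatch: int = 0,
) -> DemuxResult:
    """Assign read pairs to samples by their 7-base index tag.

    ``sample_table`` maps tag -> sample name.  Tags must be pairwise
    separated by more than ``2 * max_mismatch`` so that nearest-tag
    assignment is unambiguous; otherwise a configuration error is
    raised.  Every pair lands in exactly one sample bin or in
    ``unassigned``.
    """
    tags = list(sample_table)
    for t in tags:
        if len(t) != TAG_LEN:
            raise ValueError(f"index tag {t!r} is not {TAG_LEN} bases")
    for i, a in enumerate(tags):
        for b in tags[i + 1 :]:
            if _hamming(a, b) <= 2 * max_mismatch:
                raise ValueError(
                    f"tags {a!r} and {b!r} are within 2*max_mismatch; "
                    "demultiplexing would be ambiguous"
                )
    out: Dict[str, List[ReadPair]] = {s: [] for s in sample_table.values()}
    unassigned: List[ReadPair] = []
    for pair in pairs:
        tag = pair.index_tag
        best_sample, best_d = None, max_mismatch + 1
        if tag is not None and len(tag) == TAG_LEN:
            for t, sample in sample_table.items():
                d = _hamming(tag, t)
                if d < best_d:
                    best_sample, best_d = sample, d
        if best_sample is None:
            unassigned.append(pair)
        else:
            out[best_sample].append(pair)
    return DemuxResult(by_sample=out, unassigned=unassigned)


class ProbeAssigner:
    """Vectorised Read-2 prefix matcher against a probe catalog.

    The catalog's 40-mers are unique in their terminal 20-mer by
    construction, so a 20-base prefix is the default; full-40 matching
    is available via ``prefix_len=40``.
    """

    def __init__(
        self,
        probes: Sequence[PrimerProbe],
        prefix_len: int = 20,
        max_mismatch: int = 1,
    ):
        if not probes:
            raise ValueError("probe catalog is empty")
        self.prefix_len = prefix_len
        self.max_mismatch = max_mismatch
        self.probe_ids = [p.probe_id for p in probes]
        self._mat = np.array(
            [
                np.frombuffer(p.target_seq_40[:prefix_len].encode(), dtype=np.uint8)
                for p in probes
            ]
        )

    def assign(self, read2_seq: str) -> str:
        if len(read2_seq) < self.prefix_len:
            raise ValueError("read2 shorter than prefix_len")
        arr = np.frombuffer(
            read2_seq[: self.prefix_len].encode(), dtype=np.uint8
        )
        dists = (self._mat != arr).sum(axis=1)
        best = int(dists.min())
        if best > self.max_mismatch:
            return UNASSIGNED
        hits = np.flatnonzero(dists == best)
        if len(hits) != 1:
            return UNASSIGNED
        return self.probe_ids[int(hits[0])]


def assign_probe(
    read2_seq: str,
    probe_catalog: Sequence[PrimerProbe],
    prefix_len: int = 20,
    max_mismatch: int = 1,
) -> str:
    """Match the Read 2 prefix against the catalog; unique best hit wins,
    ties or distance > max_mismatch return ``UNASSIGNED``."""
    return ProbeAssigner(probe_catalog, prefix_len, max_mismatch).assign(read2_seq)


@dataclass(frozen=True)
class TargetCall:
    on_target: bool
    reason: Optional[str]
    distance: Optional[int]
    gray_zone: bool = False


def classify_on_target(
    aln: AlignedRead,
    probe: PrimerProbe,
    on_target_dist: int = 1000,
    max_insert: int = 1500,
    count_gray_on_target: bool = False,
) -> TargetCall:
    """Classify a Read 1 alignment against its assigned probe.

    On-target requires the same chromosome, an orientation consistent
    with extension from the probe, and a probe-to-read distance of at
    most ``on_target_dist``.  Distances in ``(on_target_dist,
    max_insert]`` are flagged as a gray zone and counted on-target only
    when ``count_gray_on_target`` is set; larger separations are
    off-target with reason ``DISTANCE_EXCEEDED``.
    """
    if not aln.mapped or aln.chrom != probe.chrom:
        return TargetCall(False, WRONG_CHROM, None)
    if aln.strand != probe.strand:
        return TargetCall(False, WRONG_ORIENTATION, None)
    if probe.strand == "+":
        if aln.end <= probe.anchor_start:
            return TargetCall(False, WRONG_ORIENTATION, None)
        distance = max(0, aln.pos - probe.anchor_end)
    else:
        if aln.pos >= probe.anchor_end:
            return TargetCall(False, WRONG_ORIENTATION, None)
        distance = max(0, probe.anchor_start - aln.end)
    if distance <= on_target_dist:
        return TargetCall(True, None, distance)
    if distance <= max_insert:
        return TargetCall(
            count_gray_on_target,
            None if count_gray_on_target else DISTANCE_EXCEEDED,
            distance,
            gray_zone=True,
        )
    return TargetCall(False, DISTANCE_EXCEEDED, distance)


@dataclass
class ProbeYieldTable:
    counts: pd.Series  # on-target read count per probe_id
    total_assigned: int
    total_on_target: int

    @property
    def capture_rate(self) -> float:
        if len(self.counts) == 0:
            return 0.0
        return float((self.counts >= 1).mean())

    @property
    def uniformity(self) -> float:
        return uniformity_1log(self.counts.to_list())


def per_probe_yield(
    classified: Iterable[Tuple[str, TargetCall]],
    probe_ids: Sequence[str],
) -> ProbeYieldTable:
    """Count on-target reads per probe over the full catalog.

    ``classified`` yields (probe_id, TargetCall) for each assigned read;
    probes with no reads appear with a zero count so the capture rate
    denominator is the whole pool.
    """
    counts = {pid: 0 for pid in probe_ids}
    total_assigned = 0
    total_on = 0
    for pid, call in classified:
        total_assigned += 1
        if call.on_target:
            total_on += 1
            if pid in counts:
                counts[pid] += 1
    series = pd.Series(counts, dtype=int)
    return ProbeYieldTable(series, total_assigned, total_on)


def uniformity_1log(yields: Sequence[float]) -> float:
    """Fraction of probes whose yield is within 10x of the median yield.

    The median is taken over all probes, zeros included; the metric is
    invariant under rescaling all yields by a positive constant.
    """
    if len(yields) == 0:
        raise ValueError("at least one probe yield is required")
    arr = np.asarray(yields, dtype=float)
    m = float(np.median(arr))
    return float(((arr >= m / 10.0) & (arr <= m * 10.0)).mean())


def _merge_intervals(intervals: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    merged: List[List[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def roi_coverage(
    alignments: Iterable[Tuple[AlignedRead, str]],
    probes: Sequence[PrimerProbe],
    flank: int = 50,
    thresholds: Sequence[int] = (1, 10, 30),
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Per-ROI mean coverage and fraction of bases at depth thresholds.

    ROIs are probe anchors enlarged by ``flank`` on each side, merged
    when overlapping.  Depth counts Read 1 genomic bases only and
    excludes any read whose alignment overlaps the 40-base footprint of
    its originating probe, so synthetic probe sequence never inflates
    coverage.  ``alignments`` yields (aligned_read, assigned_probe_id).
    """
    footprint = {p.probe_id: (p.chrom, p.anchor_start, p.anchor_end) for p in probes}
    rois: Dict[str, List[Tuple[int, int]]] = {}
    for p in probes:
        rois.setdefault(p.chrom, []).append(
            (max(0, p.anchor_start - flank), p.anchor_end + flank)
        )
    rois = {chrom: _merge_intervals(iv) for chrom, iv in rois.items()}

    lengths: Dict[str, int] = dict(chrom_lengths or {})
    aln_list = [(a, pid) for a, pid in alignments if a.mapped and a.chrom is not None]
    for a, _ in aln_list:
        lengths[a.chrom] = max(lengths.get(a.chrom, 0), a.end)
    for chrom, iv in rois.items():
        lengths[chrom] = max(lengths.get(chrom, 0), iv[-1][1])

    diff: Dict[str, np.ndarray] = {
        chrom: np.zeros(lengths[chrom] + 1, dtype=np.int64) for chrom in rois
    }
    for a, pid in aln_list:
        if a.chrom not in diff:
            continue
        fp = footprint.get(pid)
        if fp is not None and fp[0] == a.chrom and a.pos < fp[2] and a.end > fp[1]:
            continue  # read overlaps its probe's synthetic footprint
        diff[a.chrom][a.pos] += 1
        diff[a.chrom][min(a.end, lengths[a.chrom])] -= 1

    rows = []
    for chrom, intervals in rois.items():
        depth = np.cumsum(diff[chrom])[:-1]
        for s, e in intervals:
            d = depth[s:e]
            row = {
                "chrom": chrom,
                "start": s,
                "end": e,
                "mean_coverage": float(d.mean()) if len(d) else 0.0,
            }
            for th in thresholds:
                row[f"frac_ge_{th}x"] = float((d >= th).mean()) if len(d) else 0.0
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AfCall:
    called: bool
    allele_fraction: float
    reason: Optional[str] = None


def naive_af_call(
    depth: int,
    alt_count: int,
    mean_base_qual: float,
    min_coverage: int = 10,
    min_var_freq: float = 0.15,
    min_avg_qual: float = 25,
) -> AfCall:
    """Threshold allele-fraction call on one pileup column.

    A site is called when depth, variant fraction and mean base quality
    all clear their thresholds; the allele fraction is always returned.
    Mean base quality is the arithmetic mean of Phred scores.
    """
    if depth < 0 or not (0 <= alt_count <= depth):
        raise ValueError("require 0 <= alt_count <= depth")
    af = alt_count / depth if depth > 0 else 0.0
    if depth < min_coverage:
        return AfCall(False, af, "LOW_COVERAGE")
    if af < min_var_freq:
        return AfCall(False, af, "LOW_VAR_FREQ")
    if mean_base_qual < min_avg_qual:
        return AfCall(False, af, "LOW_QUALITY")
    return AfCall(True, af)


def mean_phred(qual: str, offset: int = 33) -> float:
    if not qual:
        return 0.0
    return sum(ord(c) - offset for c in qual) / len(qual)


# ---------------------------------------------------------------------------
# SAM I/O

def read_sam(path: Union[str, Path], min_mapq: int = 0) -> Dict[str, AlignedRead]:
    """Load Read 1 alignments from SAM into AlignedRead records.

    ``fully_aligned`` is true for mapped reads whose CIGAR contains only
    aligned bases (no clips, insertions or deletions against the
    reference).
    """
    out: Dict[str, AlignedRead] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_unmapped:
                out[rec.query_name] = AlignedRead(
                    read_id=rec.query_name,
                    chrom=None,
                    pos=0,
                    strand="+",
                    mapq=rec.mapping_quality,
                    aln_len=rec.query_length or 0,
                    fully_aligned=False,
                    mapped=False,
                    seq=rec.query_sequence or "",
                    qual=_qual_to_str(rec),
                )
                continue
            if rec.mapping_quality < min_mapq:
                continue
            cig = rec.cigartuples or []
            full = bool(cig) and all(op in (0, 7, 8) for op, _ in cig)
            out[rec.query_name] = AlignedRead(
                read_id=rec.query_name,
                chrom=rec.reference_name,
                pos=rec.reference_start,
                strand="-" if rec.is_reverse else "+",
                mapq=rec.mapping_quality,
                aln_len=rec.reference_length or rec.query_length or 0,
                fully_aligned=full,
                mapped=True,
                seq=rec.query_sequence or "",
                qual=_qual_to_str(rec),
            )
    return out


def _qual_to_str(rec) -> str:
    if rec.query_qualities is None:
        return ""
    return "".join(chr(q + 33) for q in rec.query_qualities)


def summarize_capture(
    alignments: Mapping[str, AlignedRead],
    read2_by_id: Mapping[str, str],
    probes: Sequence[PrimerProbe],
    prefix_len: int = 20,
    assign_max_mismatch: int = 1,
    on_target_dist: int = 1000,
    max_insert: int = 1500,
    flank: int = 50,
) -> Dict:
    """End-to-end QC report: assignment, on-target fraction, yield,
    uniformity and per-ROI coverage for one sample."""
    assigner = ProbeAssigner(probes, prefix_len, assign_max_mismatch)
    by_id = {p.probe_id: p for p in probes}
    classified: List[Tuple[str, TargetCall]] = []
    cov_input: List[Tuple[AlignedRead, str]] = []
    n_unassigned = 0
    for read_id, read2 in read2_by_id.items():
        pid = assigner.assign(read2)
        if pid == UNASSIGNED:
            n_unassigned += 1
            continue
        aln = alignments.get(read_id)
        if aln is None:
            continue
        call = classify_on_target(
            aln, by_id[pid], on_target_dist=on_target_dist, max_insert=max_insert
        )
        classified.append((pid, call))
        if call.on_target:
            cov_input.append((aln, pid))
    table = per_probe_yield(classified, [p.probe_id for p in probes])
    cov = roi_coverage(cov_input, probes, flank=flank)
    n_mapped = sum(1 for a in alignments.values() if a.mapped)
    return {
        "total_reads": len(read2_by_id),
        "mapped_reads": n_mapped,
        "assigned_reads": len(classified),
        "unassigned_reads": n_unassigned,
        "on_target_reads": table.total_on_target,
        "on_target_fraction_of_assigned": (
            table.total_on_target / len(classified) if classified else 0.0
        ),
        "capture_rate": table.capture_rate,
        "uniformity_1log": table.uniformity,
        "per_probe_counts": table.counts.to_dict(),
        "roi_coverage": cov.to_dict(orient="records"),
    }


def write_report(report: Dict, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
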