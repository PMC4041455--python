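"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by naive enumeration (window
scans, all-pairs Hamming comparisons, per-base pileup recounts,
overlap walks) so they share no code path with the implementations
they check.
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

_RC = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def brute_multiplicity(seqs: Mapping[str, str], k: int) -> Dict[str, int]:
    """Window-scan both-strand k-mer counts (palindromes once per site)."""
    out: Dict[str, int] = {}
    for seq in seqs.values():
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if "N" in w:
                continue
            out[w] = out.get(w, 0) + 1
            w_rc = rc(w)
            if w_rc != w:
                out[w_rc] = out.get(w_rc, 0) + 1
    return out


def brute_site_stats(
    seqs: Mapping[str, str], k: int
) -> Tuple[List[Tuple[str, int]], np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs exact-count and nearest-other-site Hamming distance.

    Returns (site ids, validity mask, exact site counts, min distance to
    any other site over both strands; comparisons of a site with its own
    reverse complement are excluded).
    """
    sites: List[Tuple[str, int]] = []
    windows: List[str] = []
    valid: List[bool] = []
    for name, seq in seqs.items():
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            sites.append((name, i))
            windows.append(w)
            valid.append("N" not in w)
    n = len(windows)
    enc = {c: i for i, c in enumerate("ACGTN")}
    mat = np.array([[enc[c] for c in w] for w in windows], dtype=np.uint8)
    mat_rc = np.array([[enc[c] for c in rc(w)] for w in windows], dtype=np.uint8)
    counts = np.zeros(n, dtype=int)
    min_other = np.full(n, k + 1, dtype=int)
    valid_arr = np.array(valid)
    for i in range(n):
        if not valid_arr[i]:
            continue
        d_f = (mat != mat[i]).sum(axis=1)
        d_r = (mat_rc != mat[i]).sum(axis=1)
        d_f[~valid_arr] = k + 1
        d_r[~valid_arr] = k + 1
        counts[i] = int((d_f == 0).sum() + (d_r == 0).sum())
        if windows[i] == rc(windows[i]):
            counts[i] = int((d_f == 0).sum())
        d_f[i] = k + 1  # same site, forward
        d_r[i] = k + 1  # same site, opposite strand
        min_other[i] = int(min(d_f.min(), d_r.min()))
    return sites, valid_arr, counts, min_other


def brute_classify(seqs: Mapping[str, str], k: int, margin: int) -> Dict[Tuple[str, int], str]:
    """All-pairs-derived mapability labels for every window position."""
    sites, valid, counts, min_other = brute_site_stats(seqs, k)
    labels: Dict[Tuple[str, int], str] = {}
    for idx, key in enumerate(sites):
        if not valid[idx]:
            labels[key] = "AMBIGUOUS"
        elif counts[idx] > 1:
            labels[key] = "REPETITIVE"
        elif min_other[idx] > margin:
            labels[key] = "UNIQUE_D1"
        else:
            labels[key] = "UNIQUE_STRICT"
    return labels


def brute_unique_with_margin(kmer: str, seqs: Mapping[str, str], margin: int) -> bool:
    """Hamming scan of every window (both strands) against one k-mer."""
    k = len(kmer)
    match_sites = []
    near = 0
    for name, seq in seqs.items():
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if "N" in w:
                continue
            d = min(
                sum(a != b for a, b in zip(w, kmer)),
                sum(a != b for a, b in zip(rc(w), kmer)),
            )
            if d == 0:
                match_sites.append((name, i))
            elif d <= margin:
                near += 1
    if not match_sites:
        raise ValueError("k-mer absent")
    return len(match_sites) == 1 and near == 0


def naive_pileup(
    read_intervals: Sequence[Tuple[int, int]], region: Tuple[int, int]
) -> np.ndarray:
    """Per-base depth of a region by direct counting."""
    s, e = region
    depth = np.zeros(e - s, dtype=int)
    for rs, re_ in read_intervals:
        for p in range(max(rs, s), min(re_, e)):
            depth[p - s] += 1
    return depth


def overlap_walk(reads: Sequence[str], k: int) -> Optional[str]:
    """Reconstruct the unique simple path through the read k-mers.

    Follows unique (k-1)-overlap successors from the unique source
    k-mer; returns None if the graph is not a simple path.  Works on
    the forward orientation of the reads only, so callers should
    compare up to reverse complement.
    """
    kmers = set()
    for read in reads:
        for i in range(len(read) - k + 1):
            kmers.add(read[i : i + k])
    if not kmers:
        return None
    succ: Dict[str, List[str]] = {}
    pred: Dict[str, List[str]] = {}
    for km in kmers:
        succ.setdefault(km[:-1], []).append(km)
        pred.setdefault(km[1:], []).append(km)
    starts = [km for km in kmers if len(pred.get(km[:-1], [])) == 0]
    if len(starts) != 1:
        return None
    path = [starts[0]]
    seen = {starts[0]}
    while True:
        nxts = succ.get(path[-1][1:], [])
        if len(nxts) == 0:
            break
        if len(nxts) != 1 or nxts[0] in seen:
            return None
        path.append(nxts[0])
        seen.add(nxts[0])
    if len(seen) != len(kmers):
        return None
    return path[0] + "".join(km[-1] for km in path[1:])
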