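"""k-mer multiplicity and mapability classification.

Probe placement requires that the extension-proximal 20-mer of every
probe aligns to exactly one genomic site and that no second site exists
within a small Hamming margin ("at least two edited bases to align
elsewhere").  This module builds the exact-match occurrence index and
per-position mapability track that encode those constraints.

Occurrences are counted on both strands: a k-mer and its reverse
complement describe the two faces of one physical site, and a k-mer
equal to its own reverse complement is counted once per site.  "Edit
distance" is interpreted as Hamming distance (substitutions only),
matching the interchangeable use of "mismatches" and "edited bases" in
the field.  The mismatch-margin test enumerates all substitution
neighbours of a k-mer (3k for margin 1) against the exact index, so it
scales linearly in genome length rather than quadratically.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Tuple, Union

import numpy as np

from .genome import Genome, GenomeSequence, as_genome, reverse_complement

MAX_K = 31  # 2-bit packed codes must fit a 64-bit integer

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i
_ENCODE[ord("N")] = 4


class MapabilityCode(IntEnum):
    """Per-position classification of the k-mer starting at that position."""

    UNIQUE_D1 = 0      # exactly one site, and no other site within the margin
    UNIQUE_STRICT = 1  # exactly one exact-match site, but a near-miss exists
    REPETITIVE = 2     # more than one exact-match site (either strand)
    AMBIGUOUS = 3      # window contains N


def encode_bases(seq: str) -> np.ndarray:
    """Map a sequence to uint8 codes (A,C,G,T -> 0..3, N -> 4)."""
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains non-ACGTN characters")
    return arr


def _window_codes(arr: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """2-bit packed codes for every k-window plus a validity mask (no N)."""
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(arr, k)
    valid = ~(win == 4).any(axis=1)
    pows = (np.uint64(1) << (2 * np.arange(k - 1, -1, -1, dtype=np.uint64))).astype(
        np.uint64
    )
    # N (code 4) would corrupt the packing; zero it out, masked windows are dropped.
    safe = np.where(win == 4, 0, win).astype(np.uint64)
    codes = (safe * pows).sum(axis=1, dtype=np.uint64)
    return codes, valid


def encode_kmer(kmer: str) -> int:
    arr = encode_bases(kmer)
    if (arr == 4).any():
        raise ValueError("k-mer contains N")
    code = 0
    for b in arr:
        code = (code << 2) | int(b)
    return code


def decode_kmer(code: int, k: int) -> str:
    out = []
    for i in range(k - 1, -1, -1):
        out.append("ACGT"[(code >> (2 * i)) & 3])
    return "".join(out)


def rc_code(code: int, k: int) -> int:
    """Reverse complement of a packed k-mer code (A<->T, C<->G is XOR 3)."""
    out = 0
    for _ in range(k):
        out = (out << 2) | ((code & 3) ^ 3)
        code >>= 2
    return out


def neighbor_codes(code: int, k: int, margin: int) -> Iterator[int]:
    """All packed codes at Hamming distance 1..margin from ``code``."""
    if margin <= 0:
        return
    shifts = [2 * i for i in range(k)]
    for m in range(1, margin + 1):
        for positions in itertools.combinations(shifts, m):
            for deltas in itertools.product((1, 2, 3), repeat=m):
                nb = code
                for pos, d in zip(positions, deltas):
                    nb ^= d << pos
                yield nb


class KmerIndex:
    """Exact-match occurrence index of all k-windows of a genome.

    Windows containing N are skipped.  Forward-strand window counts are
    stored; both-strand ("physical site") multiplicities are derived by
    also consulting the reverse complement.
    """

    def __init__(self, genome: Union[Genome, GenomeSequence, Mapping[str, str]], k: int):
        if k < 1:
            raise ValueError("k must be >= 1")
        if k > MAX_K:
            raise ValueError(f"k > {MAX_K} is not supported")
        self.genome = as_genome(genome)
        self.k = k
        self.codes: Dict[str, np.ndarray] = {}
        self.valid: Dict[str, np.ndarray] = {}
        counts: Dict[int, int] = {}
        short = True
        for name, rec in self.genome.items():
            arr = encode_bases(rec.seq)
            codes, valid = _window_codes(arr, k)
            self.codes[name] = codes
            self.valid[name] = valid
            if len(rec.seq) >= k:
                short = False
            for c in codes[valid].tolist():
                counts[c] = counts.get(c, 0) + 1
        if short and len(self.genome) > 0:
            warnings.warn(
                f"every sequence is shorter than k={k}; index is empty", stacklevel=2
            )
        self._fwd_counts = counts
        # Occurrence set over both orientations, for neighbour lookups.
        present = set(counts)
        for c in list(counts):
            present.add(rc_code(c, k))
        self._present = present

    def forward_count(self, code: int) -> int:
        return self._fwd_counts.get(code, 0)

    def site_count(self, code: int) -> int:
        """Number of physical sites matching ``code`` on either strand."""
        rc = rc_code(code, self.k)
        if rc == code:
            return self._fwd_counts.get(code, 0)
        return self._fwd_counts.get(code, 0) + self._fwd_counts.get(rc, 0)

    def present_either_strand(self, code: int) -> bool:
        return code in self._present

    def distinct_codes(self) -> Iterable[int]:
        return self._present

    def is_margin_unique(self, code: int, margin: int) -> bool:
        """True iff ``code`` has one site and no other site within ``margin``.

        Assumes ``site_count(code) == 1``; under that assumption the
        reverse complement of ``code`` occurs nowhere else, so it is the
        only neighbour that must be skipped (it is the same physical
        site read from the other strand).
        """
        if margin <= 0:
            return True
        rc = rc_code(code, self.k)
        for nb in neighbor_codes(code, self.k, margin):
            if nb == rc:
                continue
            if nb in self._present:
                return False
        return True


def build_multiplicity(
    genome: Union[Genome, GenomeSequence, Mapping[str, str]], k: int
) -> Dict[str, int]:
    """Both-strand occurrence counts for every k-mer observed in ``genome``.

    Each physical window contributes one count to its forward k-mer and
    one to the reverse complement of that window; a palindromic k-mer is
    counted once per site.  Windows containing N are skipped.
    """
    idx = KmerIndex(genome, k)
    return {decode_kmer(c, k): idx.site_count(c) for c in idx.distinct_codes()}


def is_unique_with_margin(
    kmer: str,
    genome: Union[Genome, GenomeSequence, Mapping[str, str]],
    margin_mismatches: int = 1,
    index: Optional[KmerIndex] = None,
) -> bool:
    """True iff ``kmer`` has exactly one genomic site and the nearest other
    site (either strand) is more than ``margin_mismatches`` substitutions away.
    """
    idx = index if index is not None else KmerIndex(genome, len(kmer))
    if len(kmer) != idx.k:
        raise ValueError("k-mer length does not match index k")
    code = encode_kmer(kmer)
    n_sites = idx.site_count(code)
    if n_sites == 0:
        raise ValueError("k-mer does not occur in the genome")
    if n_sites > 1:
        return False
    return idx.is_margin_unique(code, margin_mismatches)


@dataclass
class KmerTrack:
    """Per-position mapability classification for a fixed (k, margin).

    ``tracks[name][i]`` classifies the k-window starting at position
    ``i`` of sequence ``name``; each track has ``len(seq) - k + 1``
    entries.
    """

    k: int
    margin: int
    tracks: Dict[str, np.ndarray]
    genome_digest: str = ""

    def code_at(self, name: str, pos: int) -> MapabilityCode:
        return MapabilityCode(int(self.tracks[name][pos]))

    def track(self, name: str) -> np.ndarray:
        return self.tracks[name]

    def counts(self) -> Dict[str, int]:
        out = {c.name: 0 for c in MapabilityCode}
        for arr in self.tracks.values():
            vals, n = np.unique(arr, return_counts=True)
            for v, c in zip(vals, n):
                out[MapabilityCode(int(v)).name] += int(c)
        return out

    def to_bed(self, path: Union[str, Path]) -> None:
        """Write the track as BED (0-based half-open, name = classification).

        Runs of identical classification are merged into single records.
        """
        with open(path, "w") as fh:
            for name, arr in self.tracks.items():
                if len(arr) == 0:
                    continue
                boundaries = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate([[0], boundaries])
                ends = np.concatenate([boundaries, [len(arr)]])
                for s, e in zip(starts, ends):
                    label = MapabilityCode(int(arr[s])).name
                    fh.write(f"{name}\t{s}\t{e}\t{label}\n")

    def save(self, path: Union[str, Path]) -> None:
        meta = np.array([self.k, self.margin], dtype=np.int64)
        arrays = {f"track::{name}": arr for name, arr in self.tracks.items()}
        np.savez_compressed(
            path, __meta__=meta, __digest__=np.array(self.genome_digest), **arrays
        )

    @classmethod
    def load(cls, path: Union[str, Path]) -> "KmerTrack":
        with np.load(path, allow_pickle=False) as data:
            k, margin = (int(x) for x in data["__meta__"])
            digest = str(data["__digest__"])
            tracks = {
                key[len("track::") :]: data[key]
                for key in data.files
                if key.startswith("track::")
            }
        return cls(k=k, margin=margin, tracks=tracks, genome_digest=digest)


def classify_positions(
    genome: Union[Genome, GenomeSequence, Mapping[str, str]],
    k: int = 20,
    margin_mismatches: int = 1,
    index: Optional[KmerIndex] = None,
) -> KmerTrack:
    """Label every k-window of the genome with its mapability class."""
    idx = index if index is not None else KmerIndex(genome, k)
    tracks: Dict[str, np.ndarray] = {}
    for name in idx.genome:
        codes = idx.codes[name]
        valid = idx.valid[name]
        out = np.full(len(codes), MapabilityCode.AMBIGUOUS, dtype=np.uint8)
        site_counts = np.fromiter(
            (idx.site_count(int(c)) for c in codes), count=len(codes), dtype=np.int64
        ) if len(codes) else np.empty(0, dtype=np.int64)
        rep = valid & (site_counts > 1)
        uni = valid & (site_counts == 1)
        out[rep] = MapabilityCode.REPETITIVE
        if margin_mismatches <= 0:
            out[uni] = MapabilityCode.UNIQUE_D1
        else:
            for i in np.flatnonzero(uni):
                if idx.is_margin_unique(int(codes[i]), margin_mismatches):
                    out[i] = MapabilityCode.UNIQUE_D1
                else:
                    out[i] = MapabilityCode.UNIQUE_STRICT
        tracks[name] = out
    return KmerTrack(
        k=k, margin=margin_mismatches, tracks=tracks, genome_digest=idx.genome.digest()
    )


def cached_classify(
    genome: Union[Genome, GenomeSequence, Mapping[str, str]],
    k: int,
    margin_mismatches: int,
    cache_dir: Union[str, Path],
) -> KmerTrack:
    """Classify positions, memoised on disk keyed by (genome digest, k, margin)."""
    g = as_genome(genome)
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    key = f"{g.digest()[:16]}_k{k}_m{margin_mismatches}.npz"
    path = cache_dir / key
    if path.exists():
        track = KmerTrack.load(path)
        if track.genome_digest == g.digest():
            return track
    track = classify_positions(g, k, margin_mismatches)
    track.save(path)
    return track
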