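"""Genome-size estimation from the k-mer spectrum of a read set.

Every k-length window of every read is counted as-read (no canonical
strand collapsing), skipping windows that contain N.  The histogram of
k-mer multiplicities has a main peak at the per-k-mer sequencing depth
D; k-mers below a low-frequency cutoff (default: occurring fewer than 4
times) are treated as sequencing-error artifacts.  Genome size follows

    G = (N * (L - K + 1) - B) / D

with N reads of length L, K the k-mer size, B the number of k-mer
*instances* in the low-frequency bins, and D the spectrum peak.  B is
instance-counted (multiplicity-weighted) because the formula subtracts
it from the instance total N*(L-K+1); a distinct-k-mer variant is
available behind ``b_mode="distinct"`` with a warning.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable

import numpy as np

from .genome_io import Read

_CODE4 = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE4[_b] = _i


@dataclass
class KmerHistogram:
    """Map from multiplicity to the number of distinct k-mers at that multiplicity."""

    k: int
    counts: Dict[int, int]

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if any(m < 1 or c < 0 for m, c in self.counts.items()):
            raise ValueError("multiplicities must be >= 1 and counts >= 0")

    @property
    def total_kmers(self) -> int:
        """Total number of k-mer instances, sum(multiplicity * count)."""
        return sum(m * c for m, c in self.counts.items())


def _read_kmer_codes(seq: str, k: int) -> np.ndarray:
    """2-bit packed codes of all N-free k-windows of one read (k <= 31)."""
    codes = _CODE4[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.size < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win >= 0).all(axis=1)
    if not valid.any():
        return np.empty(0, dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return win[valid] @ powers


def count_kmers(reads: Iterable[Read], k: int) -> KmerHistogram:
    """K-mer multiplicity histogram of a read set.

    Windows containing N are skipped.  Raises when no read yields a
    single k-mer.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k <= 31:
        chunks: list[np.ndarray] = []
        for r in reads:
            c = _read_kmer_codes(r.seq, k)
            if c.size:
                chunks.append(c)
        if not chunks:
            raise ValueError(f"no k-mers: every read is shorter than k={k} "
                             "or all windows contain N")
        _, mult = np.unique(np.concatenate(chunks), return_counts=True)
        ms, cs = np.unique(mult, return_counts=True)
        return KmerHistogram(k, {int(m): int(c) for m, c in zip(ms, cs)})
    # large k: plain string counting (the packed representation needs 2k <= 62 bits)
    counter: Counter[str] = Counter()
    for r in reads:
        seq = r.seq
        for seg in seq.split("N"):
            for i in range(len(seg) - k + 1):
                counter[seg[i:i + k]] += 1
    if not counter:
        raise ValueError(f"no k-mers: every read is shorter than k={k} "
                         "or all windows contain N")
    hist: Counter[int] = Counter(counter.values())
    return KmerHistogram(k, dict(hist))


def estimate_depth(hist: KmerHistogram, cutoff: int = 4) -> int:
    """Spectrum mode at or above the low-frequency cutoff (ties -> smaller).

    This is the per-k-mer sequencing depth D of the size formula.
    """
    eligible = {m: c for m, c in hist.counts.items() if m >= cutoff}
    if not eligible:
        raise ValueError("spectrum entirely low-frequency: no multiplicity "
                         f">= cutoff {cutoff}")
    return min(eligible, key=lambda m: (-eligible[m], m))


def low_frequency_mass(hist: KmerHistogram, cutoff: int = 4,
                       b_mode: str = "instances") -> int:
    """B of the size formula: k-mer mass in bins below the cutoff.

    ``instances`` (default) weights each bin by its multiplicity;
    ``distinct`` counts distinct k-mers only.
    """
    if b_mode == "instances":
        return sum(m * c for m, c in hist.counts.items() if m < cutoff)
    if b_mode == "distinct":
        warnings.warn(
            "distinct-k-mer B is inconsistent with the instance total "
            "N*(L-K+1) the formula subtracts it from; interpret with care",
            stacklevel=2,
        )
        return sum(c for m, c in hist.counts.items() if m < cutoff)
    raise ValueError(f"unknown b_mode {b_mode!r}")


def estimate_genome_size(n_reads: int, read_length: float, k: int,
                         low_mass: int, depth: int) -> float:
    """G = (N*(L-K+1) - B) / D, in bases."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if n_reads < 1:
        raise ValueError("need at least one read")
    if read_length <= k:
        raise ValueError("read length must exceed k")
    numerator = n_reads * (read_length - k + 1) - low_mass
    if numerator <= 0:
        raise ValueError("low-frequency mass exceeds k-mer total; "
                         "estimate undefined")
    return numerator / depth


@dataclass
class GenomeSizeEstimate:
    """All quantities of the k-mer size formula, G = (N*(L-K+1)-B)/D."""

    n_reads: int          # N
    read_length: float    # L
    k: int                # K
    low_mass: int         # B
    depth: int            # D
    size: float           # G (bases)
    cutoff: int = 4

    @property
    def size_bp(self) -> int:
        return int(round(self.size))

    def as_dict(self) -> dict:
        return {"N": self.n_reads, "L": self.read_length, "K": self.k,
                "B": self.low_mass, "D": self.depth, "G": self.size,
                "cutoff": self.cutoff}


def estimate_from_reads(reads: Iterable[Read], k: int = 21, cutoff: int = 4,
                        b_mode: str = "instances") -> GenomeSizeEstimate:
    """Full pipeline: count k-mers, locate the depth peak, apply the formula.

    Reads are assumed to share one length; with mixed lengths the mean is
    used for L, which keeps N*(L-K+1) equal to the true window total.
    """
    reads = list(reads)
    if not reads:
        raise ValueError("no reads")
    n = len(reads)
    mean_len = sum(len(r) for r in reads) / n
    read_length = int(mean_len) if mean_len.is_integer() else mean_len
    hist = count_kmers(reads, k)
    depth = estimate_depth(hist, cutoff)
    b = low_frequency_mass(hist, cutoff, b_mode)
    g = estimate_genome_size(n, read_length, k, b, depth)
    return GenomeSizeEstimate(n, read_length, k, b, depth, g, cutoff)
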