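"""Maximal unique match (MUM) detection between two genomes.

A MUM is an exact match that (a) cannot be extended left or right and
(b) whose matched string occurs exactly once in the target and — under
the default ``uniqueness="both"`` — exactly once in the candidate,
counting both candidate strands.  ``uniqueness="reference_only"``
relaxes (b) to uniqueness in the target alone, the convention of
anchor-based whole-genome aligners.

The production path builds a generalized suffix array (prefix doubling)
over target + candidate forward + candidate reverse-complement with
unique sentinel codes between records; N is encoded as a unique code per
position so it never matches anything and matches never cross gap runs.
Adjacent-suffix LCPs and arbitrary longest-common-extension queries are
answered by binary lifting over the doubling rank tables.

``find_mums_naive`` is a deliberately independent brute-force
enumerator (dynamic programming over diagonals plus literal substring
occurrence counting) kept permanently as a test oracle; it refuses
inputs above a small guard bound.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np

from .genome_io import Genome, PathLike

_RC = str.maketrans("ACGTN", "TGCAN")

#: combined genome length above which the naive enumerator refuses to run
NAIVE_GUARD_BP = 20_000


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N} (N maps to N)."""
    if set(seq) - set("ACGTN"):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"invalid nucleotide characters {bad} in sequence")
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class Match:
    """One maximal unique exact match.

    ``qry_start`` is always on the candidate's forward strand (the
    leftmost matched base), also for '-' strand matches, which keeps all
    interval arithmetic uniform.
    """

    ref_id: str
    ref_start: int
    qry_id: str
    qry_start: int
    length: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.length < 1 or self.ref_start < 0 or self.qry_start < 0:
            raise ValueError("negative coordinate or non-positive length")

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.length

    @property
    def qry_end(self) -> int:
        return self.qry_start + self.length

    def sort_key(self):
        return (self.ref_id, self.ref_start, self.qry_id, self.qry_start,
                self.strand, self.length)


@dataclass(frozen=True)
class MumParams:
    min_length: int = 20
    uniqueness: str = "both"  # or "reference_only"

    def __post_init__(self) -> None:
        if self.min_length < 2:
            raise ValueError("min_length must be >= 2")
        if self.uniqueness not in ("both", "reference_only"):
            raise ValueError(f"unknown uniqueness mode {self.uniqueness!r}")


# ---------------------------------------------------------------------------
# suffix-array machinery

_LUT = np.zeros(256, dtype=np.int64)
for _i, _b in enumerate(b"ACGT", start=1):
    _LUT[_b] = _i


def _encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 1..4; anything else (N) -> 0, later replaced by unique codes."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class _Index:
    """Concatenation of target, candidate(+) and candidate(-) with sentinels."""

    def __init__(self, target: Genome, candidate: Genome):
        self.target = target
        self.candidate = candidate
        chunks: list[np.ndarray] = []
        origin: list[np.ndarray] = []
        rec: list[np.ndarray] = []
        off: list[np.ndarray] = []
        sep = np.zeros(1, dtype=np.int64)

        def add(codes: np.ndarray, o: int, r: int) -> None:
            m = codes.size
            chunks.append(codes)
            origin.append(np.full(m, o, dtype=np.int8))
            rec.append(np.full(m, r, dtype=np.int64))
            off.append(np.arange(m, dtype=np.int64))
            chunks.append(sep)
            origin.append(np.full(1, 3, dtype=np.int8))
            rec.append(np.full(1, -1, dtype=np.int64))
            off.append(np.zeros(1, dtype=np.int64))

        for ri, r in enumerate(target.records):
            add(_encode(r.seq), 0, ri)
        for ri, r in enumerate(candidate.records):
            add(_encode(r.seq), 1, ri)
        for ri, r in enumerate(candidate.records):
            add(_encode(reverse_complement(r.seq)), 2, ri)

        s = np.concatenate(chunks)
        special = np.nonzero(s == 0)[0]
        s[special] = 5 + np.arange(special.size, dtype=np.int64)
        self.s = s
        self.origin = np.concatenate(origin)
        self.rec = np.concatenate(rec)
        self.off = np.concatenate(off)
        self.n = s.size
        self.target_ids = [r.id for r in target.records]
        self.cand_ids = [r.id for r in candidate.records]
        self.cand_lens = np.array([len(r) for r in candidate.records], dtype=np.int64)


def _suffix_array(s: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    """Prefix-doubling suffix array; returns (sa, rank tables for lengths 2^p)."""
    n = s.size
    order = np.argsort(s, kind="stable")
    rank = np.empty(n, dtype=np.int64)
    sr = s[order]
    newg = np.ones(n, dtype=bool)
    newg[1:] = sr[1:] != sr[:-1]
    rank[order] = np.cumsum(newg) - 1
    ranks = [rank.copy()]
    k = 1
    while rank.max() < n - 1 and k < n:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        r1 = rank[order]
        r2 = key2[order]
        newg = np.ones(n, dtype=bool)
        newg[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        rank = np.empty(n, dtype=np.int64)
        rank[order] = np.cumsum(newg) - 1
        ranks.append(rank.copy())
        k <<= 1
    return order, ranks


def _lce(i: np.ndarray, j: np.ndarray, ranks: list[np.ndarray], n: int) -> np.ndarray:
    """Vectorized longest common extension between suffix pairs (binary lifting)."""
    i = np.asarray(i, dtype=np.int64)
    j = np.asarray(j, dtype=np.int64)
    out = np.zeros(i.shape, dtype=np.int64)
    for p in range(len(ranks) - 1, -1, -1):
        k = 1 << p
        ii = i + out
        jj = j + out
        ok = (ii + k <= n) & (jj + k <= n)
        eq = np.zeros(i.shape, dtype=bool)
        idx = np.nonzero(ok)[0]
        if idx.size:
            eq[idx] = ranks[p][ii[idx]] == ranks[p][jj[idx]]
        out += np.where(eq, k, 0)
    return out


def _emit(index: _Index, ii: np.ndarray, jj: np.ndarray, ll: np.ndarray) -> List[Match]:
    """Map (target pos, candidate-side pos, length) triples to Match objects."""
    out: list[Match] = []
    for i, j, l in zip(ii.tolist(), jj.tolist(), ll.tolist()):
        ref_id = index.target_ids[index.rec[i]]
        ref_start = int(index.off[i])
        qrec = index.rec[j]
        qry_id = index.cand_ids[qrec]
        if index.origin[j] == 1:
            strand = "+"
            qry_start = int(index.off[j])
        else:
            strand = "-"
            qry_start = int(index.cand_lens[qrec] - index.off[j] - l)
        out.append(Match(ref_id, ref_start, qry_id, qry_start, int(l), strand))
    out.sort(key=Match.sort_key)
    return out


def find_mums(target: Genome, candidate: Genome,
              params: MumParams = MumParams()) -> List[Match]:
    """All maximal matches of length >= ``params.min_length`` satisfying the
    uniqueness mode, sorted by (ref_id, ref_start, qry_id, qry_start)."""
    index = _Index(target, candidate)
    sa, ranks = _suffix_array(index.s)
    n = index.n
    lcp = np.zeros(n, dtype=np.int64)
    if n > 1:
        lcp[1:] = _lce(sa[:-1], sa[1:], ranks, n)
    orig = index.origin[sa]
    s = index.s

    if params.uniqueness == "both":
        l = lcp[1:]                      # l[k] = LCP(sa[k], sa[k+1])
        oa, ob = orig[:-1], orig[1:]
        cross = ((oa == 0) & ((ob == 1) | (ob == 2))) | \
                ((ob == 0) & ((oa == 1) | (oa == 2)))
        left_n = lcp[:-1]                # LCP(sa[k-1], sa[k]); lcp[0] == 0
        right_n = np.append(lcp[2:], 0)  # LCP(sa[k+1], sa[k+2])
        keep = cross & (l >= params.min_length) & (left_n < l) & (right_n < l)
        ks = np.nonzero(keep)[0]
        a, b = sa[ks], sa[ks + 1]
        ii = np.where(orig[ks] == 0, a, b)
        jj = np.where(orig[ks] == 0, b, a)
        ll = l[ks]
        ok = (ii == 0) | (jj == 0)
        inner = ~ok
        ok[inner] = s[ii[inner] - 1] != s[jj[inner] - 1]  # left-maximality
        return _emit(index, ii[ok], jj[ok], ll[ok])

    # reference_only: for each candidate-side suffix, match against the
    # nearest target suffix (in SA order) achieving the maximal extension.
    idx = np.arange(n)
    is_t = orig == 0
    prev_t = np.where(is_t, idx, -1)
    np.maximum.accumulate(prev_t, out=prev_t)
    next_t = np.where(is_t, idx, n)
    next_t = np.minimum.accumulate(next_t[::-1])[::-1]

    q = np.nonzero((orig == 1) | (orig == 2))[0]
    pt, nt = prev_t[q], next_t[q]
    la = np.full(q.size, -1, dtype=np.int64)
    lb = np.full(q.size, -1, dtype=np.int64)
    m = pt >= 0
    if m.any():
        la[m] = _lce(sa[q[m]], sa[pt[m]], ranks, n)
    m = nt < n
    if m.any():
        lb[m] = _lce(sa[q[m]], sa[nt[m]], ranks, n)
    l = np.maximum(la, lb)
    keep = (l >= params.min_length) & (la != lb)
    q, pt, nt, la, lb, l = q[keep], pt[keep], nt[keep], la[keep], lb[keep], l[keep]
    partner = np.where(la > lb, pt, nt)

    # uniqueness in target: the partner's target neighbors must not share
    # a prefix of the match length (else the matched string repeats in T).
    t_above = np.where(partner > 0, prev_t[np.maximum(partner - 1, 0)], -1)
    t_below = np.where(partner < n - 1, next_t[np.minimum(partner + 1, n - 1)], n)
    ua = np.full(q.size, -1, dtype=np.int64)
    ub = np.full(q.size, -1, dtype=np.int64)
    m = t_above >= 0
    if m.any():
        ua[m] = _lce(sa[partner[m]], sa[t_above[m]], ranks, n)
    m = t_below < n
    if m.any():
        ub[m] = _lce(sa[partner[m]], sa[t_below[m]], ranks, n)
    keep = (ua < l) & (ub < l)
    q, partner, l = q[keep], partner[keep], l[keep]

    ii, jj = sa[partner], sa[q]
    ok = (ii == 0) | (jj == 0)
    inner = ~ok
    ok[inner] = s[ii[inner] - 1] != s[jj[inner] - 1]
    return _emit(index, ii[ok], jj[ok], l[ok])


# ---------------------------------------------------------------------------
# brute-force oracle

def _count_overlapping(text: str, pat: str) -> int:
    c = 0
    i = text.find(pat)
    while i >= 0:
        c += 1
        i = text.find(pat, i + 1)
    return c


def _diagonal_maximal_matches(x: np.ndarray, y: np.ndarray,
                              min_length: int) -> list[tuple[int, int, int]]:
    """(i, j, length) of all left/right-maximal exact runs, by diagonal DP."""
    eq = x[:, None] == y[None, :]
    out: list[tuple[int, int, int]] = []
    n, m = x.size, y.size
    for d in range(-(n - 1), m):
        v = np.diagonal(eq, offset=d)
        hits = np.nonzero(v)[0]
        if hits.size == 0:
            continue
        breaks = np.nonzero(np.diff(hits) > 1)[0]
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [hits.size - 1]))
        for s0, e0 in zip(starts, ends):
            t0 = int(hits[s0])
            run = int(hits[e0]) - t0 + 1
            if run < min_length:
                continue
            if d >= 0:
                out.append((t0, t0 + d, run))
            else:
                out.append((t0 - d, t0, run))
    return out


def find_mums_naive(target: Genome, candidate: Genome,
                    params: MumParams = MumParams()) -> List[Match]:
    """Exhaustive-enumeration reference implementation of :func:`find_mums`.

    Same contract, computed by diagonal dynamic programming plus literal
    occurrence counting.  Refuses inputs whose combined length exceeds
    ``NAIVE_GUARD_BP`` to keep the quadratic enumeration tractable.
    """
    total = target.total_length + candidate.total_length
    if total > NAIVE_GUARD_BP:
        raise ValueError(
            f"combined genome length {total} bp exceeds the naive-oracle "
            f"guard bound of {NAIVE_GUARD_BP} bp"
        )
    t_strings = [r.seq for r in target.records]
    c_fwd = [r.seq for r in candidate.records]
    c_rev = [reverse_complement(s) for s in c_fwd]

    def enc(seq: str, nfill: int) -> np.ndarray:
        codes = _encode(seq)
        codes[codes == 0] = nfill  # N: different fill per side => never equal
        return codes

    raw: list[tuple[Match, str]] = []
    for tr in target.records:
        x = enc(tr.seq, -1)
        for qi, qr in enumerate(candidate.records):
            for strand, ystr in (("+", c_fwd[qi]), ("-", c_rev[qi])):
                y = enc(ystr, -2)
                for i, j, run in _diagonal_maximal_matches(x, y, params.min_length):
                    w = tr.seq[i:i + run]
                    qs = j if strand == "+" else len(ystr) - j - run
                    raw.append((Match(tr.id, i, qr.id, qs, run, strand), w))

    out: list[Match] = []
    for match, w in raw:
        if sum(_count_overlapping(t, w) for t in t_strings) != 1:
            continue
        if params.uniqueness == "both":
            occ = sum(_count_overlapping(c, w) for c in c_fwd)
            occ += sum(_count_overlapping(c, w) for c in c_rev)
            if occ != 1:
                continue
        out.append(match)
    out.sort(key=Match.sort_key)
    return out


# ---------------------------------------------------------------------------
# tab-separated serialization (PAF-like columns)

_TSV_HEADER = ("qry_id", "qry_len", "qry_start", "qry_end", "strand",
               "ref_id", "ref_len", "ref_start", "ref_end", "match_length")


def write_matches_tsv(matches: Sequence[Match], path: PathLike,
                      target: Optional[Genome] = None,
                      candidate: Optional[Genome] = None) -> None:
    """Write matches as tab-separated text with PAF-like columns.

    Sequence lengths are filled from the genomes when provided, else 0.
    Starts are 0-based half-open; ends exclusive.
    """
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_TSV_HEADER) + "\n")
        for m in matches:
            qlen = len(candidate[m.qry_id]) if candidate else 0
            rlen = len(target[m.ref_id]) if target else 0
            fh.write("\t".join(map(str, (
                m.qry_id, qlen, m.qry_start, m.qry_end, m.strand,
                m.ref_id, rlen, m.ref_start, m.ref_end, m.length))) + "\n")


def read_matches_tsv(path: PathLike) -> List[Match]:
    out: list[Match] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != len(_TSV_HEADER):
                raise ValueError(f"{path}: expected {len(_TSV_HEADER)} columns, "
                                 f"got {len(f)}")
            out.append(Match(f[5], int(f[7]), f[0], int(f[2]), int(f[9]), f[4]))
    return out
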