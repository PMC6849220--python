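"""One-to-one filtering of MUM sets by weighted collinear chaining.

The goal mirrors classical delta-filter "-1" semantics: keep a subset of
matches in which no target region and no candidate region is aligned
more than once, preferring subsets of maximal total matched bases.
Weight is matched bases (match length); MUMs are exact so no identity
weighting applies.  A conflicting match is dropped whole — no trimming.

Two execution paths share one contract:

* small inputs (<= EXACT_LIMIT matches) are solved exactly by
  branch-and-bound over feasible subsets (feasible = pairwise
  non-overlapping on both axes and non-crossing within a
  (ref, qry, strand) group);
* larger inputs use per-group maximum-weight collinear chaining
  (Fenwick-tree weighted LIS, O(n log n)) followed by greedy cross-group
  conflict resolution in order of descending chain weight.

Both are deterministic; ties prefer the chain whose first match has the
smallest (ref_start, qry_start).
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right, insort
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .genome_io import Genome
from .mum_engine import Match

#: at or below this many matches the exact branch-and-bound solver runs
EXACT_LIMIT = 16

_GroupKey = Tuple[str, str, str]


@dataclass
class Chain:
    """A collinear, non-overlapping run of matches on one (ref, qry, strand)."""

    matches: List[Match]
    weight: int


def _group_key(m: Match) -> _GroupKey:
    return (m.ref_id, m.qry_id, m.strand)


def _overlap(a0: int, a1: int, b0: int, b1: int) -> bool:
    return a0 < b1 and b0 < a1


def _compatible(a: Match, b: Match) -> bool:
    """May ``a`` and ``b`` coexist in a one-to-one set?"""
    if a.ref_id == b.ref_id and _overlap(a.ref_start, a.ref_end,
                                         b.ref_start, b.ref_end):
        return False
    if a.qry_id == b.qry_id and _overlap(a.qry_start, a.qry_end,
                                         b.qry_start, b.qry_end):
        return False
    if _group_key(a) == _group_key(b):
        first, second = (a, b) if a.ref_start < b.ref_start else (b, a)
        if a.strand == "+":
            if second.qry_start < first.qry_start:  # crossing
                return False
        else:
            if second.qry_start > first.qry_start:
                return False
    return True


# ---------------------------------------------------------------------------
# exact small-instance solver

def _exact_filter(ms: List[Match]) -> List[Match]:
    """Branch-and-bound maximum-weight feasible subset (include-first DFS).

    Include-first exploration over matches in canonical order makes the
    first optimum found the one whose first retained match is earliest,
    matching the chain tie-break convention.
    """
    n = len(ms)
    w = [m.length for m in ms]
    incompat = [0] * n
    for i in range(n):
        for j in range(i + 1, n):
            if not _compatible(ms[i], ms[j]):
                incompat[i] |= 1 << j
                incompat[j] |= 1 << i
    suffix = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        suffix[i] = suffix[i + 1] + w[i]

    best_w = -1
    best_sel: list[int] = []

    def dfs(i: int, blocked: int, cur_w: int, sel: list[int]) -> None:
        nonlocal best_w, best_sel
        if cur_w + suffix[i] <= best_w:
            return
        if i == n:
            if cur_w > best_w:
                best_w = cur_w
                best_sel = sel.copy()
            return
        if not blocked & (1 << i):
            sel.append(i)
            dfs(i + 1, blocked | incompat[i], cur_w + w[i], sel)
            sel.pop()
        dfs(i + 1, blocked, cur_w, sel)

    dfs(0, 0, 0, [])
    return [ms[i] for i in best_sel]


# ---------------------------------------------------------------------------
# chaining path for large inputs

class _MaxFenwick:
    """Fenwick tree over prefix maxima of comparable tuples."""

    def __init__(self, size: int):
        self.size = size
        self.tree: list[Optional[tuple]] = [None] * (size + 1)

    def update(self, i: int, value: tuple) -> None:
        i += 1
        while i <= self.size:
            if self.tree[i] is None or value > self.tree[i]:
                self.tree[i] = value
            i += i & (-i)

    def query(self, i: int) -> Optional[tuple]:
        """Max over positions [0, i]; None when empty or i < 0."""
        best: Optional[tuple] = None
        i += 1
        while i > 0:
            t = self.tree[i]
            if t is not None and (best is None or t > best):
                best = t
            i -= i & (-i)
        return best


def _chain_coords(m: Match) -> tuple[int, int]:
    """(start, end) on the candidate axis, mirrored for '-' so that a valid
    chain is strictly increasing and non-overlapping in these coordinates."""
    if m.strand == "+":
        return m.qry_start, m.qry_end
    return -m.qry_end, -m.qry_start


def chain_group(matches: Sequence[Match]) -> Chain:
    """Maximum-weight collinear chain of matches sharing (ref, qry, strand).

    Among equal-weight optima the chain whose first match has the
    smallest ref_start (then qry_start) wins.
    """
    ms = list(matches)
    if not ms:
        return Chain([], 0)
    keys = {_group_key(m) for m in ms}
    if len(keys) != 1:
        raise ValueError(f"chain_group needs a single (ref, qry, strand) group, "
                         f"got {sorted(keys)}")
    ms.sort(key=Match.sort_key)
    n = len(ms)
    qs = [_chain_coords(m)[0] for m in ms]
    qe = [_chain_coords(m)[1] for m in ms]
    all_qe = sorted(set(qe))
    comp = {v: i for i, v in enumerate(all_qe)}

    by_end = sorted(range(n), key=lambda i: (ms[i].ref_end, i))
    order = sorted(range(n), key=lambda i: (ms[i].ref_start, qs[i], i))
    fen = _MaxFenwick(len(all_qe))
    score = [0] * n
    parent = [-1] * n
    start_rank = [0] * n
    ptr = 0
    for j in order:
        while ptr < n and ms[by_end[ptr]].ref_end <= ms[j].ref_start:
            i = by_end[ptr]
            fen.update(comp[qe[i]], (score[i], -start_rank[i], -i, i))
            ptr += 1
        # predecessors must end at qs[j] or before on the candidate axis
        ci = bisect_right(all_qe, qs[j]) - 1
        best = fen.query(ci)
        if best is None:
            score[j] = ms[j].length
            parent[j] = -1
            start_rank[j] = j
        else:
            score[j] = best[0] + ms[j].length
            parent[j] = best[3]
            start_rank[j] = start_rank[best[3]]

    end = max(range(n), key=lambda j: (score[j], -start_rank[j], -j))
    chain: list[Match] = []
    while end != -1:
        chain.append(ms[end])
        end = parent[end]
    chain.reverse()
    return Chain(chain, sum(m.length for m in chain))


class _Occupancy:
    """Per-sequence sorted disjoint intervals with overlap queries."""

    def __init__(self) -> None:
        self._by_id: Dict[str, list[tuple[int, int]]] = {}

    def conflicts(self, seq_id: str, start: int, end: int) -> bool:
        iv = self._by_id.get(seq_id)
        if not iv:
            return False
        k = bisect_left(iv, (start, start))
        if k < len(iv) and iv[k][0] < end:
            return True
        if k > 0 and iv[k - 1][1] > start:
            return True
        return False

    def add(self, seq_id: str, start: int, end: int) -> None:
        insort(self._by_id.setdefault(seq_id, []), (start, end))


def _chained_greedy(ms: List[Match]) -> List[Match]:
    groups: Dict[_GroupKey, list[Match]] = {}
    for m in ms:
        groups.setdefault(_group_key(m), []).append(m)
    chains = [chain_group(g) for g in groups.values()]
    chains.sort(key=lambda c: (-c.weight, c.matches[0].sort_key()))
    occ_ref = _Occupancy()
    occ_qry = _Occupancy()
    kept: list[Match] = []
    for chain in chains:
        for m in chain.matches:
            if occ_ref.conflicts(m.ref_id, m.ref_start, m.ref_end):
                continue
            if occ_qry.conflicts(m.qry_id, m.qry_start, m.qry_end):
                continue
            occ_ref.add(m.ref_id, m.ref_start, m.ref_end)
            occ_qry.add(m.qry_id, m.qry_start, m.qry_end)
            kept.append(m)
    kept.sort(key=Match.sort_key)
    return kept


def filter_one_to_one(matches: Sequence[Match],
                      target: Optional[Genome] = None,
                      candidate: Optional[Genome] = None) -> List[Match]:
    """Reduce a raw match set to a one-to-one consistent subset.

    All matches must belong to one (target, candidate) genome pair; when
    the genomes are supplied, membership of every ref_id/qry_id is
    verified and a mixed input raises ``ValueError``.  Output is sorted,
    a subset of the input, pairwise non-overlapping on both axes, and
    idempotent under re-filtering.
    """
    ms = sorted(matches, key=Match.sort_key)
    if not ms:
        return []
    if target is not None:
        bad = {m.ref_id for m in ms if m.ref_id not in target}
        if bad:
            raise ValueError(f"matches reference unknown target sequence(s) "
                             f"{sorted(bad)}: mixed genome pairs?")
    if candidate is not None:
        bad = {m.qry_id for m in ms if m.qry_id not in candidate}
        if bad:
            raise ValueError(f"matches reference unknown candidate sequence(s) "
                             f"{sorted(bad)}: mixed genome pairs?")
    if len(ms) <= EXACT_LIMIT:
        out = _exact_filter(ms)
        out.sort(key=Match.sort_key)
        return out
    return _chained_greedy(ms)
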