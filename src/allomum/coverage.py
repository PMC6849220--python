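"""Per-species and pairwise cumulative coverage of a target genome.

The single-species statistic is the percentage of target bases covered
by the union of that species' (filtered) match intervals.  The pairwise
"cumulative alignment percentage" is the percentage covered by the union
of two species' interval sets — union, not sum, so it can never exceed
100% and two species covering the same regions gain nothing.  Ranking
all pairs by this statistic nominates the progenitor pair of an
allopolyploid target: each true progenitor covers its own subgenome
strongly, so the true pair dominates the union.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .genome_io import Genome
from .mum_engine import Match

IntervalMap = Dict[str, "IntervalSet"]


@dataclass
class IntervalSet:
    """Sorted, disjoint, half-open intervals on one target sequence."""

    seq_id: str
    intervals: List[Tuple[int, int]] = field(default_factory=list)

    @property
    def covered_bp(self) -> int:
        return sum(e - s for s, e in self.intervals)


def merge_intervals(pairs: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Union of half-open intervals; adjacent intervals are merged."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(pairs):
        if s >= e:
            raise ValueError(f"empty or inverted interval ({s}, {e})")
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def merge_to_intervals(matches: Sequence[Match], target: Genome) -> IntervalMap:
    """Per target sequence, the merged union of match footprints."""
    raw: dict[str, list[tuple[int, int]]] = {}
    for m in matches:
        if m.ref_id not in target:
            raise ValueError(f"match on unknown target sequence {m.ref_id!r}")
        if m.ref_end > len(target[m.ref_id]):
            raise ValueError(
                f"match [{m.ref_start}, {m.ref_end}) out of bounds on "
                f"{m.ref_id!r} (length {len(target[m.ref_id])})"
            )
        raw.setdefault(m.ref_id, []).append((m.ref_start, m.ref_end))
    return {sid: IntervalSet(sid, merge_intervals(iv)) for sid, iv in raw.items()}


def _union_maps(a: IntervalMap, b: IntervalMap) -> IntervalMap:
    out: IntervalMap = {}
    for sid in sorted(set(a) | set(b)):
        pairs = []
        if sid in a:
            pairs.extend(a[sid].intervals)
        if sid in b:
            pairs.extend(b[sid].intervals)
        out[sid] = IntervalSet(sid, merge_intervals(pairs))
    return out


def _covered_bp(intervals: IntervalMap) -> int:
    return sum(iv.covered_bp for iv in intervals.values())


@dataclass
class CoverageReport:
    """Coverage of the target genome by one candidate species."""

    species: str
    covered_bp: int
    target_bp: int

    @property
    def percent(self) -> float:
        return 100.0 * self.covered_bp / self.target_bp


def mums_percentage(intervals: IntervalMap, target: Genome,
                    species: str = "") -> CoverageReport:
    """Percentage of the target covered by one species' merged intervals.

    Reported to two decimals in human-facing outputs; full precision here.
    """
    if target.total_length == 0:
        raise ValueError("target genome has zero length")
    for sid, iv in intervals.items():
        if sid not in target:
            raise ValueError(f"interval set on unknown target sequence {sid!r}")
        if iv.intervals and iv.intervals[-1][1] > len(target[sid]):
            raise ValueError(f"interval beyond end of {sid!r}")
    return CoverageReport(species, _covered_bp(intervals), target.total_length)


def cumulative_pair_percentage(intervals_a: IntervalMap, intervals_b: IntervalMap,
                               target: Genome) -> float:
    """Percent of the target covered by the union of two species' intervals."""
    if target.total_length == 0:
        raise ValueError("target genome has zero length")
    return 100.0 * _covered_bp(_union_maps(intervals_a, intervals_b)) \
        / target.total_length


@dataclass
class PairCoverageMatrix:
    """Symmetric matrix of cumulative pair percentages.

    The diagonal holds single-species percentages; off-diagonal entries
    are union-of-pair percentages, hence always >= the larger diagonal
    entry and <= min(100, sum of the two diagonals).
    """

    species: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        k = len(self.species)
        if v.shape != (k, k):
            raise ValueError(f"matrix shape {v.shape} does not fit "
                             f"{k} species")
        if not np.allclose(v, v.T):
            raise ValueError("pair coverage matrix must be symmetric")
        self.values = v

    def single(self, name: str) -> float:
        return float(self.values[self.species.index(name)][self.species.index(name)])

    def pair(self, a: str, b: str) -> float:
        return float(self.values[self.species.index(a)][self.species.index(b)])


def pair_coverage_matrix(per_species: Mapping[str, IntervalMap],
                         target: Genome) -> PairCoverageMatrix:
    """Build the full pair matrix from per-species interval maps.

    Species order in the matrix is sorted by name, so the result is
    invariant to input ordering.
    """
    names = sorted(per_species)
    k = len(names)
    v = np.zeros((k, k))
    for i, a in enumerate(names):
        v[i, i] = mums_percentage(per_species[a], target, a).percent
    for i, j in combinations(range(k), 2):
        p = cumulative_pair_percentage(per_species[names[i]],
                                       per_species[names[j]], target)
        v[i, j] = v[j, i] = p
    return PairCoverageMatrix(names, v)


def rank_pairs(matrix: PairCoverageMatrix) -> List[Tuple[str, str, float]]:
    """All unordered candidate pairs, best cumulative percentage first.

    Ties break lexicographically by species names; the first element is
    the nominated progenitor pair.
    """
    if len(matrix.species) < 2:
        raise ValueError("fewer than 2 candidates: no pairs to rank")
    pairs = [
        (a, b, matrix.pair(a, b))
        for a, b in combinations(sorted(matrix.species), 2)
    ]
    pairs.sort(key=lambda t: (-t[2], t[0], t[1]))
    return pairs
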