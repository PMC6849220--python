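"""Synthetic allotetraploid scenarios with known progenitor truth.

The generator emulates the study design this package targets: a panel
of related genomes radiating from one common ancestor (star phylogeny)
at controlled divergences, an allotetraploid target whose two subgenomes
descend from two distinct panel lineages and then diverge further after
hybridization, and uniform shotgun reads with a flat per-base error
rate.  Everything is bit-reproducible under a fixed seed.

Default scenario parameters: a 200 kb ancestor in 2 chromosomes at GC
0.36 (the GC content typical of the crucifer assemblies this mimics),
six candidate lineages spanning divergences 0.03-0.20 substitutions per
site with the two progenitors at 0.05, post-hybridization divergence
0.02, indels at 1e-3 events/site up to 10 bp, and 2 inversions per
lineage to mimic pre-hybridization chromosome rearrangement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genome_io import Genome, Read, SequenceRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_B2I = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_I2B_ARR = np.frombuffer(b"ACGTN", dtype=np.uint8)
# complement in code space; N (4) is its own complement
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
_ENC_LUT = np.zeros(256, dtype=np.uint8)
for _ch, _v in _B2I.items():
    _ENC_LUT[ord(_ch)] = _v


def _to_codes(seq: str) -> np.ndarray:
    """A,C,G,T,N -> 0..4."""
    return _ENC_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _to_seq(arr: np.ndarray) -> str:
    return _I2B_ARR[arr].tobytes().decode("ascii")

DEFAULT_PANEL: Tuple[Tuple[str, float], ...] = (
    ("lineageA", 0.03),
    ("lineageB", 0.05),
    ("lineageC", 0.05),
    ("lineageD", 0.075),
    ("lineageE", 0.12),
    ("lineageF", 0.20),
)


@dataclass
class SyntheticScenario:
    """Study-condition parameters of one synthetic allotetraploid scenario."""

    ancestor_length: int = 200_000
    n_chromosomes: int = 2
    gc: float = 0.36
    panel: Tuple[Tuple[str, float], ...] = DEFAULT_PANEL
    progenitors: Tuple[str, str] = ("lineageB", "lineageC")
    post_hybrid_divergence: float = 0.02
    indel_rate: float = 1e-3
    indel_max: int = 10
    n_inversions: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        names = [n for n, _ in self.panel]
        if len(set(names)) != len(names):
            raise ValueError("panel names must be unique")
        for n, d in self.panel:
            if not 0 <= d < 0.5:
                raise ValueError(f"divergence of {n!r} must be in [0, 0.5)")
        if not 0 <= self.post_hybrid_divergence < 0.5:
            raise ValueError("post_hybrid_divergence must be in [0, 0.5)")
        a, b = self.progenitors
        if a == b:
            raise ValueError("progenitors must be two distinct panel members")
        for p in self.progenitors:
            if p not in names:
                raise ValueError(f"progenitor {p!r} not in panel")


@dataclass
class ScenarioTruth:
    """A generated scenario plus its ground truth."""

    target: Genome
    candidates: List[Genome]
    true_pair: Tuple[str, str]

    def __post_init__(self) -> None:
        names = {g.name for g in self.candidates}
        if not set(self.true_pair) <= names:
            raise ValueError("true_pair names must appear among candidates")


def simulate_ancestor(length: int, n_chromosomes: int = 1, gc: float = 0.5,
                      seed: int = 0, name: str = "ancestor") -> Genome:
    """I.i.d. random genome with the given GC content, split into
    near-equal chromosomes (remainder bases go to the first ones)."""
    if not 0 < gc < 1:
        raise ValueError("gc must be strictly between 0 and 1")
    if not 1 <= n_chromosomes <= length:
        raise ValueError("need length >= n_chromosomes >= 1")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draws = rng.choice(4, size=length, p=p)
    base, extra = divmod(length, n_chromosomes)
    records = []
    pos = 0
    for i in range(n_chromosomes):
        n = base + (1 if i < extra else 0)
        seq = _BASES[draws[pos:pos + n]].tobytes().decode("ascii")
        records.append(SequenceRecord(f"chr{i + 1}", seq))
        pos += n
    return Genome(name, records)


@dataclass
class EvolveLog:
    """Coordinates of the mutations applied by :func:`evolve` (pre-mutation
    coordinates of the input genome)."""

    inversions: List[Tuple[str, int, int]] = field(default_factory=list)
    n_substitutions: int = 0
    n_insertions: int = 0
    n_deletions: int = 0


def _pick_segments(rng: np.random.Generator, length: int,
                   n: int) -> List[Tuple[int, int]]:
    """Up to ``n`` non-overlapping segments, each 1-5% of the sequence."""
    lo = max(2, length // 100)
    hi = max(lo + 1, length // 20)
    chosen: list[tuple[int, int]] = []
    attempts = 0
    while len(chosen) < n and attempts < 50 * max(n, 1):
        attempts += 1
        seg = int(rng.integers(lo, hi + 1))
        if seg >= length:
            continue
        start = int(rng.integers(0, length - seg + 1))
        end = start + seg
        if any(start < e and s < end for s, e in chosen):
            continue
        chosen.append((start, end))
    return sorted(chosen)


def evolve(genome: Genome, sub_rate: float, indel_rate: float = 0.0,
           indel_max: int = 1, n_inversions: int = 0, seed: int = 0,
           name: Optional[str] = None) -> Genome:
    """Derive a descendant genome; see :func:`evolve_with_log`."""
    return evolve_with_log(genome, sub_rate, indel_rate, indel_max,
                           n_inversions, seed, name)[0]


def evolve_with_log(genome: Genome, sub_rate: float, indel_rate: float = 0.0,
                    indel_max: int = 1, n_inversions: int = 0, seed: int = 0,
                    name: Optional[str] = None) -> Tuple[Genome, EvolveLog]:
    """Apply, in order: inversions, substitutions, indels.

    * ``n_inversions`` non-overlapping random segments (1-5% of their
      chromosome each) are reverse-complemented, the budget spread over
      chromosomes proportionally to length;
    * each non-N site mutates to one of the three other bases with
      probability ``sub_rate``;
    * indel events arrive with per-site probability ``indel_rate``
      (Poisson-thinned), length uniform on [1, indel_max], insertion and
      deletion equiprobable, inserted bases uniform over {A,C,G,T}.

    Returns the evolved genome and a log with the inversion coordinates
    (on the input genome) and mutation tallies.
    """
    if not 0 <= sub_rate < 1 or not 0 <= indel_rate < 1:
        raise ValueError("rates must be in [0, 1)")
    if indel_max < 1:
        raise ValueError("indel_max must be >= 1")
    rng = np.random.default_rng(seed)
    log = EvolveLog()

    # spread the inversion budget over records, largest first
    lens = np.array([len(r) for r in genome.records], dtype=float)
    inv_per_rec = np.zeros(len(lens), dtype=int)
    if n_inversions > 0:
        picks = rng.choice(len(lens), size=n_inversions, p=lens / lens.sum())
        for p in picks:
            inv_per_rec[p] += 1

    records: list[SequenceRecord] = []
    for ri, rec in enumerate(genome.records):
        arr = _to_codes(rec.seq)

        for start, end in _pick_segments(rng, arr.size, int(inv_per_rec[ri])):
            arr[start:end] = _COMP[arr[start:end]][::-1]
            log.inversions.append((rec.id, start, end))

        if sub_rate > 0:
            hit = np.nonzero((rng.random(arr.size) < sub_rate) & (arr < 4))[0]
            if hit.size:
                arr[hit] = (arr[hit] + rng.integers(1, 4, size=hit.size)) % 4
                log.n_substitutions += int(hit.size)

        if indel_rate > 0:
            n_events = rng.poisson(indel_rate * arr.size)
            if n_events:
                pos = np.sort(rng.integers(0, arr.size, size=n_events))[::-1]
                is_ins = rng.random(n_events) < 0.5
                sizes = rng.integers(1, indel_max + 1, size=n_events)
                for p, ins, sz in zip(pos.tolist(), is_ins.tolist(),
                                      sizes.tolist()):
                    if ins:
                        arr = np.insert(arr, p,
                                        rng.integers(0, 4, size=sz).astype(np.uint8))
                        log.n_insertions += 1
                    else:
                        arr = np.delete(arr, np.s_[p:p + int(sz)])
                        log.n_deletions += 1
        if arr.size == 0:  # pathological deletion of a whole record
            arr = rng.integers(0, 4, size=1).astype(np.uint8)
        records.append(SequenceRecord(rec.id, _to_seq(arr), rec.description))
    return Genome(name if name is not None else genome.name, records), log


def make_scenario(cfg: SyntheticScenario) -> ScenarioTruth:
    """Generate one scenario: ancestor -> panel -> allotetraploid target.

    The target is the concatenation of the two progenitors' genomes,
    each further evolved by ``post_hybrid_divergence`` (with the same
    indel and inversion machinery), records renamed ``subgenomeA_*`` /
    ``subgenomeB_*``.  Candidates are the panel genomes as evolved, with
    no post-hybridization mutation.  ``true_pair`` is name-sorted.
    """
    rng = np.random.default_rng(cfg.seed)
    seeds = rng.integers(0, 2**31 - 1, size=len(cfg.panel) + 3)
    ancestor = simulate_ancestor(cfg.ancestor_length, cfg.n_chromosomes,
                                 cfg.gc, int(seeds[0]))
    candidates: list[Genome] = []
    by_name: Dict[str, Genome] = {}
    for i, (pname, div) in enumerate(cfg.panel):
        g = evolve(ancestor, div, cfg.indel_rate, cfg.indel_max,
                   cfg.n_inversions, int(seeds[i + 1]), name=pname)
        candidates.append(g)
        by_name[pname] = g

    sub_records: list[SequenceRecord] = []
    for label, pname, s in (("subgenomeA", cfg.progenitors[0], seeds[-2]),
                            ("subgenomeB", cfg.progenitors[1], seeds[-1])):
        sub = evolve(by_name[pname], cfg.post_hybrid_divergence,
                     cfg.indel_rate, cfg.indel_max, cfg.n_inversions, int(s))
        for rec in sub:
            sub_records.append(
                SequenceRecord(f"{label}_{rec.id}", rec.seq, rec.description))
    target = Genome("hybrid", sub_records)
    return ScenarioTruth(target, candidates, tuple(sorted(cfg.progenitors)))


def simulate_reads(genome: Genome, depth: float, read_length: int = 125,
                   error_rate: float = 0.0, seed: int = 0) -> List[Read]:
    """Uniformly placed single-end reads at the given fold-coverage.

    The read count is round(depth * genome_length / read_length); each
    base is flipped to a random different base with probability
    ``error_rate``.  Reads come from the forward strand only (strand has
    no effect on any statistic computed downstream of a k-mer histogram
    that does not canonicalize).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    shortest = min(len(r) for r in genome.records)
    if read_length > shortest:
        raise ValueError(f"read_length {read_length} exceeds the shortest "
                         f"record ({shortest} bp)")
    rng = np.random.default_rng(seed)
    n_reads = int(round(depth * genome.total_length / read_length))
    starts_per_rec = np.array([len(r) - read_length + 1 for r in genome.records],
                              dtype=float)
    p = starts_per_rec / starts_per_rec.sum()
    rec_pick = rng.choice(len(genome.records), size=n_reads, p=p)
    reads: list[Read] = []
    width = len(str(max(n_reads, 1)))
    for i in range(n_reads):
        rec = genome.records[int(rec_pick[i])]
        start = int(rng.integers(0, len(rec) - read_length + 1))
        arr = _to_codes(rec.seq[start:start + read_length])
        if error_rate > 0:
            hit = np.nonzero((rng.random(read_length) < error_rate) & (arr < 4))[0]
            if hit.size:
                arr[hit] = (arr[hit] + rng.integers(1, 4, size=hit.size)) % 4
        reads.append(Read(f"read_{i:0{width}d}", _to_seq(arr)))
    return reads
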