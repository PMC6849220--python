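from itertools import combinations

import numpy as np
import pytest

from allomum.genome_io import Genome, SequenceRecord
from allomum.mum_engine import Match
from allomum.synteny_filter import (EXACT_LIMIT, Chain, _chained_greedy,
                                    chain_group, filter_one_to_one)


def m(ref_start, qry_start, length, strand="+", ref="r", qry="q"):
    return Match(ref, ref_start, qry, qry_start, length, strand)


# --- independent oracle: bitmask DP over all feasible subsets ---------------

def _pairwise_ok(a, b):
    if a.ref_id == b.ref_id and a.ref_start < b.ref_end and b.ref_start < a.ref_end:
        return False
    if a.qry_id == b.qry_id and a.qry_start < b.qry_end and b.qry_start < a.qry_end:
        return False
    if (a.ref_id, a.qry_id, a.strand) == (b.ref_id, b.qry_id, b.strand):
        first, second = (a, b) if a.ref_start < b.ref_start else (b, a)
        inc = second.qry_start > first.qry_start
        if (a.strand == "+") != inc:
            return False
    return True


def brute_force_optimum(matches):
    """Max total weight over all pairwise-feasible subsets (enumeration)."""
    n = len(matches)
    bad = [0] * n
    for i in range(n):
        for j in range(i + 1, n):
            if not _pairwise_ok(matches[i], matches[j]):
                bad[i] |= 1 << j
                bad[j] |= 1 << i
    best = 0
    for mask in range(1 << n):
        w = 0
        ok = True
        mm = mask
        while mm:
            i = (mm & -mm).bit_length() - 1
            if bad[i] & mask:
                ok = False
                break
            w += matches[i].length
            mm &= mm - 1
        if ok and w > best:
            best = w
    return best


def random_match_set(rng, n, n_qry=2, strands="+-"):
    out = []
    for _ in range(n):
        length = int(rng.integers(5, 60))
        out.append(Match("r", int(rng.integers(0, 300)),
                         f"q{rng.integers(1, n_qry + 1)}",
                         int(rng.integers(0, 300)), length,
                         strands[int(rng.integers(0, len(strands)))]))
    return out


def assert_one_to_one(kept):
    for a, b in combinations(kept, 2):
        if a.ref_id == b.ref_id:
            assert not (a.ref_start < b.ref_end and b.ref_start < a.ref_end), \
                f"target-axis overlap: {a} vs {b}"
        if a.qry_id == b.qry_id:
            assert not (a.qry_start < b.qry_end and b.qry_start < a.qry_end), \
                f"candidate-axis overlap: {a} vs {b}"


class TestFilterOneToOne:
    def test_empty_and_singleton(self):
        assert filter_one_to_one([]) == []
        single = m(0, 0, 30)
        assert filter_one_to_one([single]) == [single]

    def test_target_axis_conflict_resolved_by_weight(self):
        big = m(0, 0, 100)
        small = m(50, 500, 30)
        assert filter_one_to_one([big, small]) == [big]

    def test_matches_exhaustive_optimum_on_small_sets(self):
        rng = np.random.default_rng(99)
        for _ in range(40):
            ms = random_match_set(rng, int(rng.integers(2, 13)))
            kept = filter_one_to_one(ms)
            assert_one_to_one(kept)
            assert set(kept) <= set(ms)
            assert sum(x.length for x in kept) == brute_force_optimum(ms)

    def test_idempotent_on_both_paths(self):
        rng = np.random.default_rng(5)
        for n in (10, 40):  # exact path and chained-greedy path
            ms = random_match_set(rng, n)
            once = filter_one_to_one(ms)
            assert filter_one_to_one(once) == once

    def test_large_path_output_is_feasible_subset(self):
        rng = np.random.default_rng(17)
        ms = random_match_set(rng, 120, n_qry=3)
        assert len(ms) > EXACT_LIMIT
        kept = filter_one_to_one(ms)
        assert set(kept) <= set(ms)
        assert sum(x.length for x in kept) <= sum(x.length for x in ms)
        assert_one_to_one(kept)

    def test_greedy_path_agrees_with_exact_when_conflict_free(self):
        # far-apart collinear matches: nothing conflicts, both paths keep all
        ms = [m(i * 100, i * 100, 50) for i in range(5)]
        assert _chained_greedy(sorted(ms, key=Match.sort_key)) == \
            sorted(ms, key=Match.sort_key)

    def test_mixed_genome_pair_detection(self):
        t = Genome("t", [SequenceRecord("r", "ACGT" * 100)])
        c = Genome("c", [SequenceRecord("q1", "ACGT" * 100)])
        alien = Match("other_chr", 0, "q1", 0, 20, "+")
        with pytest.raises(ValueError, match="mixed"):
            filter_one_to_one([alien], target=t, candidate=c)
        alien2 = Match("r", 0, "alien_q", 0, 20, "+")
        with pytest.raises(ValueError, match="mixed"):
            filter_one_to_one([alien2], target=t, candidate=c)


class TestChainGroup:
    def test_collinear_matches_all_retained(self):
        ms = [m(0, 0, 20), m(30, 25, 20), m(60, 50, 20)]
        chain = chain_group(ms)
        assert chain.matches == ms
        assert chain.weight == 60

    def test_crossing_matches_heavier_wins(self):
        a = m(0, 100, 40)
        b = m(50, 10, 60)  # crosses a on the candidate axis
        chain = chain_group([a, b])
        assert chain.matches == [b]
        assert chain.weight == 60

    def test_equal_weight_tie_breaks_to_smaller_ref_start(self):
        a = m(0, 100, 50)
        b = m(60, 10, 50)
        chain = chain_group([a, b])
        assert chain.matches == [a]

    def test_reverse_strand_chains_decrease_in_qry(self):
        ms = [m(0, 200, 20, "-"), m(30, 100, 20, "-"), m(60, 10, 20, "-")]
        chain = chain_group(ms)
        assert chain.matches == ms
        assert chain.weight == 60
        # increasing qry on '-' strand would cross: only one survives
        bad = [m(0, 10, 20, "-"), m(30, 100, 25, "-")]
        assert chain_group(bad).weight == 25

    def test_chain_group_optimum_matches_enumeration(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            n = int(rng.integers(2, 11))
            ms = random_match_set(rng, n, n_qry=1, strands="+")
            chain = chain_group(ms)
            assert chain.weight == brute_force_optimum(ms)
            assert_one_to_one(chain.matches)

    def test_mixed_group_rejected(self):
        with pytest.raises(ValueError, match="single"):
            chain_group([m(0, 0, 20, "+"), m(40, 40, 20, "-")])
        assert chain_group([]) == Chain([], 0)
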