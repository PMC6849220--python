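import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allomum.genome_io import Genome, SequenceRecord
from allomum.mum_engine import (Match, MumParams, find_mums, find_mums_naive,
                                read_matches_tsv, reverse_complement,
                                write_matches_tsv)
from conftest import random_genome

DNA = st.text(alphabet="ACGTN", min_size=1, max_size=200)


class TestReverseComplement:
    def test_known_values(self):
        assert reverse_complement("ACGT") == "ACGT"
        assert reverse_complement("AAAC") == "GTTT"
        assert reverse_complement("ANT") == "ANT"

    @given(DNA)
    @settings(deadline=None)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq

    def test_invalid_character(self):
        with pytest.raises(ValueError):
            reverse_complement("ACGU")


def _g(name, *seqs):
    return Genome(name, [SequenceRecord(f"{'rq'[name == 'c']}{i + 1}", s)
                         for i, s in enumerate(seqs)])


class TestFindMums:
    def test_identical_repeat_free_sequences_give_one_full_mum(self):
        t = _g("t", "GATTACACAT")
        c = _g("c", "GATTACACAT")
        expected = [Match("r1", 0, "q1", 0, 10, "+")]
        assert find_mums(t, c, MumParams(5)) == expected
        assert find_mums_naive(t, c, MumParams(5)) == expected

    def test_no_shared_substring_on_either_strand(self):
        t = _g("t", "AAAAAAAAAA")
        c = _g("c", "CCCCCCCCCC")
        assert find_mums(t, c, MumParams(4)) == []
        assert find_mums_naive(t, c, MumParams(4)) == []

    def test_short_repeat_structure_oracle_frozen(self):
        # every maximal common string here is unique on both sides:
        # TACGT (forward) and ACGTA (via the reverse strand); values
        # frozen from the brute-force enumerator.
        t = _g("t", "ACGTACGT")
        c = _g("c", "TACGTT")
        expected = [
            Match("r1", 0, "q1", 0, 5, "-"),
            Match("r1", 3, "q1", 0, 5, "+"),
        ]
        got = find_mums(t, c, MumParams(4))
        assert got == expected
        assert find_mums_naive(t, c, MumParams(4)) == expected

    def test_self_alignment_spans_whole_sequence(self):
        t = random_genome("t", 300, seed=5)
        c = Genome("c", [SequenceRecord("q1", t.records[0].seq)])
        mums = find_mums(t, c, MumParams(20))
        assert mums == [Match("s1", 0, "q1", 0, 300, "+")]

    def test_matches_never_cross_an_n_run(self):
        rng = np.random.default_rng(9)
        x = "".join(rng.choice(list("ACGT"), size=40))
        y = "".join(rng.choice(list("ACGT"), size=40))
        t = _g("t", x + "N" + y)
        c = _g("c", x + "A" + y)  # a full-length match would cross the N
        mums = find_mums(t, c, MumParams(10))
        assert len(mums) >= 2
        for m in mums:
            segment = t[m.ref_id].seq[m.ref_start:m.ref_end]
            assert "N" not in segment
        assert find_mums_naive(t, c, MumParams(10)) == mums

    @pytest.mark.parametrize("uniqueness", ["both", "reference_only"])
    @pytest.mark.parametrize("min_length", [5, 10])
    def test_oracle_equivalence_random_pairs(self, uniqueness, min_length):
        rng = np.random.default_rng(min_length * 1000 + len(uniqueness))
        for trial in range(12):
            lt = int(rng.integers(50, 600))
            lc = int(rng.integers(50, 600))
            gc = float(rng.uniform(0.3, 0.7))
            t = random_genome("t", lt, gc, int(rng.integers(1 << 30)),
                              n_records=1 + trial % 2)
            c = random_genome("c", lc, gc, int(rng.integers(1 << 30)))
            params = MumParams(min_length, uniqueness)
            assert find_mums(t, c, params) == find_mums_naive(t, c, params)

    def test_every_match_satisfies_string_equality_invariant(self):
        t = random_genome("t", 800, seed=11)
        c = random_genome("c", 800, seed=12)
        # make shared islands so there is something to find
        seq = t.records[0].seq[100:400] + c.records[0].seq[300:]
        c = Genome("c", [SequenceRecord("q1", seq)])
        mums = find_mums(t, c, MumParams(15))
        assert mums  # the construction guarantees shared material
        seen = set()
        for m in mums:
            assert m not in seen
            seen.add(m)
            ref = t[m.ref_id].seq[m.ref_start:m.ref_end]
            qry = c[m.qry_id].seq[m.qry_start:m.qry_end]
            if m.strand == "+":
                assert ref == qry
            else:
                assert ref == reverse_complement(qry)

    def test_strand_symmetry_under_candidate_reverse_complement(self):
        t = random_genome("t", 500, seed=21)
        c0 = random_genome("c", 500, seed=22)
        seq = c0.records[0].seq[:250] + t.records[0].seq[100:300]
        c = Genome("c", [SequenceRecord("q1", seq)])
        rc = Genome("c", [SequenceRecord("q1", reverse_complement(seq))])
        fwd = find_mums(t, c, MumParams(12))
        rev = find_mums(t, rc, MumParams(12))
        n = len(seq)
        remapped = sorted(
            (Match(m.ref_id, m.ref_start, m.qry_id,
                   n - m.qry_start - m.length, m.length,
                   "+" if m.strand == "-" else "-") for m in rev),
            key=Match.sort_key)
        assert remapped == fwd

    def test_naive_guard_bound(self):
        t = random_genome("t", 15000, seed=1)
        c = random_genome("c", 15000, seed=2)
        with pytest.raises(ValueError, match="guard"):
            find_mums_naive(t, c)

    def test_min_length_validation(self):
        with pytest.raises(ValueError):
            MumParams(min_length=1)
        with pytest.raises(ValueError):
            MumParams(uniqueness="query_only")


def test_matches_tsv_round_trip(tmp_path):
    t = random_genome("t", 400, seed=31)
    c = random_genome("c", 400, seed=31)  # same seed: plenty of matches
    mums = find_mums(t, c, MumParams(10))
    p = tmp_path / "m.tsv"
    write_matches_tsv(mums, p, t, c)
    assert read_matches_tsv(p) == mums
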