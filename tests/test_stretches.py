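"""AT-stretch scanner: examples, exhaustive-enumeration oracle, invariants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from xsilence import (GenomeSequence, GenomicInterval, count_at_steps,
                      find_at_stretches, mark_bound, representative_stretches,
                      stretch_bin_matrix)
from xsilence.stretches import ATStretch


def brute_at_steps(seq: str) -> int:
    return sum(seq[i:i + 2] in ("AT", "TA") for i in range(len(seq) - 1))


def oracle_stretches(seq: str, k: int, min_length: int):
    """All substrings that start/end on A/T with <= k interruptions,
    reduced to maximal ones, as (start, end) pairs."""
    n = len(seq)
    at = [c in "AT" for c in seq]
    cands = set()
    for s in range(n):
        if not at[s]:
            continue
        bad = 0
        for e in range(s + 1, n + 1):
            if not at[e - 1]:
                bad += 1
                continue
            if bad > k:
                break
            cands.add((s, e))
    maximal = {
        (s, e) for (s, e) in cands
        if not any(c != (s, e) and c[0] <= s and c[1] >= e for c in cands)
    }
    return sorted((s, e) for (s, e) in maximal if e - s >= min_length)


dna = st.text(alphabet="ACGT", min_size=1, max_size=300)
dna_n = st.text(alphabet="ACGTN", min_size=1, max_size=120)


class TestCountATSteps:
    @pytest.mark.parametrize("seq,expected", [
        ("ATATAT", 5),
        ("AAAA", 0),
        ("TTAAGTA", 2),
        ("AT", 1),
        ("AGTC", 0),
    ])
    def test_examples(self, seq, expected):
        assert count_at_steps(seq) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            count_at_steps("")

    @given(dna)
    def test_matches_pairwise_oracle(self, seq):
        assert count_at_steps(seq) == brute_at_steps(seq)

    @given(dna)
    def test_invariant_under_at_gc_swap(self, seq):
        swapped = seq.translate(str.maketrans("ATGC", "TACG"))
        assert count_at_steps(seq) == count_at_steps(swapped)


class TestFindATStretches:
    def test_single_pure_stretch(self):
        got = find_at_stretches(GenomeSequence("s", "AAAATTTT"), 0, 4)
        assert len(got) == 1
        st = got[0]
        assert (st.interval.start, st.interval.end) == (0, 8)
        assert st.gc_interruptions == 0
        assert st.at_steps == 1

    def test_no_at_terminus(self):
        assert find_at_stretches(GenomeSequence("s", "GGGGG"), 2, 2) == []

    def test_interrupted_stretch(self):
        got = find_at_stretches(GenomeSequence("s", "AAAAGAAAA"), 1, 8)
        assert [(s.interval.start, s.interval.end, s.gc_interruptions)
                for s in got] == [(0, 9, 1)]

    def test_min_length_validated(self):
        with pytest.raises(ValueError):
            find_at_stretches(GenomeSequence("s", "ATAT"), 0, 1)

    @given(dna, st.integers(0, 5), st.sampled_from([4, 10, 14]))
    def test_matches_enumeration_oracle(self, seq, k, min_length):
        genome = GenomeSequence("s", seq)
        got = [(s.interval.start, s.interval.end)
               for s in find_at_stretches(genome, k, min_length)]
        assert got == oracle_stretches(seq, k, min_length)

    @given(dna, st.integers(0, 5))
    def test_reported_counts_are_exact(self, seq, k):
        for s in find_at_stretches(GenomeSequence("s", seq), k, 4):
            sub = seq[s.interval.start:s.interval.end]
            assert sub[0] in "AT" and sub[-1] in "AT"
            assert sum(c not in "AT" for c in sub) == s.gc_interruptions
            assert s.gc_interruptions <= k
            assert s.at_steps == brute_at_steps(sub)
            assert s.at_steps <= s.length - 1

    @given(dna)
    def test_no_overlap_without_interruptions(self, seq):
        got = find_at_stretches(GenomeSequence("s", seq), 0, 2)
        for a, b in zip(got, got[1:]):
            assert a.interval.end <= b.interval.start

    @given(dna, st.integers(1, 5))
    def test_no_containment_among_reported(self, seq, k):
        got = [(s.interval.start, s.interval.end)
               for s in find_at_stretches(GenomeSequence("s", seq), k, 2)]
        for a in got:
            for b in got:
                if a != b:
                    assert not (b[0] <= a[0] and a[1] <= b[1])

    @given(dna_n, st.integers(0, 3))
    def test_n_acts_as_interruption(self, seq, k):
        """N can never terminate a stretch and counts against the budget."""
        for s in find_at_stretches(GenomeSequence("s", seq), k, 2):
            sub = seq[s.interval.start:s.interval.end]
            assert sub[0] in "AT" and sub[-1] in "AT"
            assert sum(c in "GCN" for c in sub) <= k


class TestMarkBound:
    peak = GenomicInterval("s", 15, 100)

    def _one(self, start, end, peaks, min_overlap=1):
        st = ATStretch(GenomicInterval("s", start, end), 0, 0)
        return mark_bound([st], peaks, min_overlap)[0].is_bound

    def test_overlapping_peak_is_bound(self):
        assert self._one(10, 20, [self.peak])

    def test_adjacent_half_open_not_bound(self):
        assert not self._one(10, 20, [GenomicInterval("s", 20, 30)])

    def test_min_overlap_threshold(self):
        assert not self._one(10, 20, [GenomicInterval("s", 19, 30)],
                             min_overlap=2)
        assert self._one(10, 20, [GenomicInterval("s", 18, 30)], min_overlap=2)


class TestBinMatrix:
    def _mk(self, length, bound):
        return ATStretch(GenomicInterval("s", 0, length), 0, 0,
                         is_bound=bound)

    def test_counts_and_fraction(self):
        sts = [self._mk(10, True), self._mk(11, False), self._mk(12, False)]
        m = stretch_bin_matrix(sts, [(10, 13)], "interruptions", [(0, 0)])
        assert m.counts[0, 0] == 3
        assert m.bound_fraction[0, 0] == pytest.approx(1 / 3)

    def test_empty_cell_is_nan(self):
        m = stretch_bin_matrix([self._mk(10, True)], [(10, 13), (14, 30)],
                               "interruptions", [(0, 0)])
        assert np.isnan(m.bound_fraction[1, 0])

    def test_marginals_conserve_total(self, rng):
        sts = [self._mk(int(rng.integers(10, 40)), bool(rng.integers(2)))
               for _ in range(200)]
        m = stretch_bin_matrix(sts, [(10, 13), (14, 30), (31, 50)],
                               "interruptions")
        assert m.counts.sum() == 200

    def test_overlapping_bins_rejected(self):
        with pytest.raises(ValueError):
            stretch_bin_matrix([], [(10, 20), (15, 30)], "interruptions",
                               [(0, 0)])

    def test_at_steps_axis(self):
        sts = [ATStretch(GenomicInterval("s", 0, 10), 0, 5, is_bound=True)]
        m = stretch_bin_matrix(sts, [(10, 13)], "at_steps", [(0, 4), (5, 9)])
        assert m.counts[0, 1] == 1 and m.counts[0, 0] == 0


def test_representative_prefers_motif_then_length():
    region = GenomicInterval("s", 0, 100)
    short_m = ATStretch(GenomicInterval("s", 5, 20), 0, 0, has_motif=True)
    long_nm = ATStretch(GenomicInterval("s", 30, 80), 0, 0)
    assert representative_stretches([short_m, long_nm], [region]) == [long_nm]
    assert representative_stretches([short_m, long_nm], [region],
                                    prefer_motif=True) == [short_m]
    # region with no overlapping stretch is skipped
    far = GenomicInterval("s", 500, 600)
    assert representative_stretches([short_m], [far]) == []
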