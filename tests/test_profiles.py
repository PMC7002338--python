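"""Rolling profiles, peak centering, classification and TSS geometry."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from xsilence import (CoverageTrack, Gene, GenomicInterval, OccupancyPeak,
                      TSSRecord, assign_tss, center_and_orient, classify_peak,
                      gc_fraction, locate_max, overlay_mean, rolling_profile,
                      tss_relative_positions)


class TestGcFraction:
    @pytest.mark.parametrize("seq,expected", [
        ("GGCC", 1.0), ("ATAT", 0.0), ("ACGT", 0.5), ("GCNN", 1.0),
    ])
    def test_examples(self, seq, expected):
        assert gc_fraction(seq) == pytest.approx(expected)

    def test_all_n_rejected(self):
        with pytest.raises(ValueError):
            gc_fraction("NNN")


def naive_rolling(values, window, step):
    L = len(values)
    return [float(np.mean(values[g:g + window]))
            for g in range(0, L - window + 1, step)]


class TestRollingProfile:
    def test_constant_input(self):
        p = rolling_profile(np.full(120, 3.5))
        assert np.allclose(p.values, 3.5)

    def test_grid_point_count(self):
        p = rolling_profile(np.zeros(100), window=50, step=10)
        assert len(p.grid) == 6

    def test_step_ramp(self):
        p = rolling_profile("G" * 50 + "A" * 50)
        assert np.allclose(p.values, [1.0, 0.8, 0.6, 0.4, 0.2, 0.0])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            rolling_profile(np.zeros(49), window=50)

    @given(st.integers(50, 500), st.integers(0, 2 ** 31 - 1))
    def test_matches_naive_oracle(self, length, seed):
        values = np.random.default_rng(seed).random(length)
        p = rolling_profile(values, window=50, step=10)
        np.testing.assert_allclose(p.values, naive_rolling(values, 50, 10),
                                   atol=1e-12)

    def test_gc_windows_exclude_n(self):
        # 25 G + 25 N: windowed GC counts only unambiguous bases
        p = rolling_profile("G" * 25 + "N" * 25)
        assert p.values[0] == pytest.approx(1.0)


class TestLocateMax:
    def test_leftmost_tie(self):
        track = CoverageTrack("c", [0, 1, 3, 3, 2])
        assert locate_max(track, GenomicInterval("c", 0, 5)) == 2

    def test_single_base(self):
        track = CoverageTrack("c", [0, 7, 0])
        assert locate_max(track, GenomicInterval("c", 1, 2)) == 1

    def test_monotone_increasing(self):
        track = CoverageTrack("c", np.arange(10.0))
        assert locate_max(track, GenomicInterval("c", 0, 10)) == 9

    def test_all_zero_warns_and_returns_leftmost(self):
        track = CoverageTrack("c", np.zeros(10))
        with pytest.warns(UserWarning):
            assert locate_max(track, GenomicInterval("c", 3, 8)) == 3


class TestCenterAndOrient:
    def _profile(self):
        return rolling_profile(np.arange(200.0), window=50, step=10)

    def _peak(self, maxpos):
        return OccupancyPeak(GenomicInterval("c", 0, 200), maxpos)

    def test_plus_strand_maps_anchor_to_zero(self):
        c = center_and_orient(self._profile(), self._peak(100), "+")
        assert 0 in c.grid
        # window midpoints are at 25, 35, ...; anchor nearest 100
        i = np.flatnonzero(c.grid == 0)[0]
        assert c.values[i] == self._profile().values[i]

    def test_minus_strand_mirrors(self):
        p = self._profile()
        c = center_and_orient(p, self._peak(100), "-")
        assert c.orientation == "flipped"
        assert list(c.values) == list(p.values[::-1])

    def test_double_flip_is_identity(self):
        p = self._profile()
        once = center_and_orient(p, self._peak(100), "-")
        # flipping the flipped grid/values reproduces the centered original
        again = np.array(once.values[::-1])
        centered = center_and_orient(p, self._peak(100), "+")
        np.testing.assert_array_equal(again, centered.values)
        np.testing.assert_array_equal(-once.grid[::-1], centered.grid)


class TestOverlayMean:
    def _p(self, grid, values):
        from xsilence.profiles import Profile
        return Profile(np.array(grid), np.array(values), 50, 10)

    def test_identical_profiles(self):
        p = self._p([0, 10], [1.0, 2.0])
        m = overlay_mean([p, p])
        np.testing.assert_array_equal(m.values, [1.0, 2.0])

    def test_pointwise_mean(self):
        m = overlay_mean([self._p([0], [1.0]), self._p([0], [3.0])])
        assert m.values[0] == 2.0

    def test_single_profile_identity(self):
        p = self._p([0, 10, 20], [1.0, 2.0, 3.0])
        m = overlay_mean([p])
        np.testing.assert_array_equal(m.values, p.values)
        np.testing.assert_array_equal(m.grid, p.grid)

    def test_min_profiles_drops_sparse_points(self):
        m = overlay_mean([self._p([0, 10], [1.0, 5.0]), self._p([0], [3.0])],
                         min_profiles=2)
        assert m.grid.tolist() == [0]

    def test_mixed_steps_rejected(self):
        from xsilence.profiles import Profile
        a = Profile(np.array([0]), np.array([1.0]), 50, 10)
        b = Profile(np.array([0]), np.array([1.0]), 50, 5)
        with pytest.raises(ValueError):
            overlay_mean([a, b])


class TestClassifyPeak:
    @pytest.mark.parametrize("width,expected", [
        (600, "class1"), (1000, "class2"), (850, "class1"), (500, "class1"),
        (499, "unclassified"), (851, "class2"),
    ])
    def test_boundaries(self, width, expected):
        assert classify_peak(width) == expected

    def test_positive_width_required(self):
        with pytest.raises(ValueError):
            classify_peak(0)


class TestAssignTss:
    gene = Gene("c", 1000, 2000, "+", "g1")
    gene_rev = Gene("c", 3000, 4000, "-", "g2")

    def _tss(self, pos, strand="+", score=1.0):
        return TSSRecord(position=pos, strand=strand, enrichment_score=score,
                         seq_id="c")

    def test_within_500_upstream_assigned(self):
        (rec,) = assign_tss([self._tss(900)], [self.gene])
        assert rec.assigned_gene == "g1"

    def test_beyond_500_unassigned(self):
        (rec,) = assign_tss([self._tss(400)], [self.gene])
        assert rec.assigned_gene is None

    def test_wrong_strand_unassigned(self):
        (rec,) = assign_tss([self._tss(900, "-")], [self.gene])
        assert rec.assigned_gene is None

    def test_minus_strand_upstream_is_rightward(self):
        (rec,) = assign_tss([self._tss(4100, "-")], [self.gene_rev])
        assert rec.assigned_gene == "g2"

    def test_ranking_by_enrichment(self):
        recs = assign_tss([self._tss(900, score=4), self._tss(950, score=9)],
                          [self.gene])
        by_pos = {r.position: r.rank for r in recs}
        assert by_pos == {950: 1, 900: 2}


class TestTssRelativePositions:
    def _setup(self, strand):
        peak = OccupancyPeak(GenomicInterval("c", 500, 1500), 1000, "g")
        return {"g": peak}, {"g": strand}

    def _tss(self, pos, rank=1):
        return TSSRecord(position=pos, strand="+", enrichment_score=1.0,
                         assigned_gene="g", rank=rank, seq_id="c")

    def test_tss_at_max_is_zero(self):
        peaks, strands = self._setup("+")
        d, *_ = tss_relative_positions([self._tss(1000)], peaks, strands)
        assert d == [0]

    def test_downstream_positive_on_plus(self):
        """A peak maximum 27 bp downstream of the TSS puts the TSS at -27."""
        peaks, strands = self._setup("+")
        d, *_ = tss_relative_positions([self._tss(973)], peaks, strands)
        assert d == [-27]

    def test_mirrored_gene_negates(self):
        peaks, strands = self._setup("-")
        d, *_ = tss_relative_positions([self._tss(973)], peaks, strands)
        assert d == [27]

    def test_missing_peak_skipped_with_warning(self):
        peaks, strands = self._setup("+")
        other = TSSRecord(position=10, strand="+", enrichment_score=1.0,
                          assigned_gene="nope", rank=1)
        with pytest.warns(UserWarning):
            d, counts, edges, top = tss_relative_positions(
                [self._tss(1000), other], peaks, strands)
        assert d == [0] and counts.sum() == 1

    def test_top_rank_flagged(self):
        peaks, strands = self._setup("+")
        d, _, _, top = tss_relative_positions(
            [self._tss(1000, rank=1), self._tss(990, rank=2)], peaks, strands)
        assert top == [True, False]
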