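import logging
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import matrix, random_intervals
from oracles import brute_background_regions, brute_best_site, two_pass_pearson
from peakvar import motif
from peakvar.core import GenomicInterval, PeakSet, SequenceSet
from peakvar.motif import PWMatrix


def uniform_pwm(L=4):
    return PWMatrix(probs=np.full((L, 4), 0.25))


def sharp_pwm(L=2, p=0.97):
    rest = (1 - p) / 3
    row = [p, rest, rest, rest]  # strongly prefers A
    return PWMatrix(probs=np.array([row] * L))


def random_seq(rng, n, with_n=False):
    alphabet = "ACGTN" if with_n else "ACGT"
    probs = [0.23, 0.23, 0.23, 0.23, 0.08] if with_n else None
    return "".join(rng.choice(list(alphabet), size=n, p=probs))


class TestFloor:
    def test_renormalization_arithmetic(self):
        pwm = PWMatrix(probs=np.array([[1.0, 0.0, 0.0, 0.0]]))
        out = motif.apply_probability_floor(pwm, 0.01)
        np.testing.assert_allclose(
            out.probs[0], np.array([1.0, 0.01, 0.01, 0.01]) / 1.03, rtol=1e-12
        )

    def test_floor_zero_identity(self):
        pwm = sharp_pwm()
        out = motif.apply_probability_floor(pwm, 0.0)
        np.testing.assert_array_equal(out.probs, pwm.probs)

    def test_uniform_unchanged(self):
        out = motif.apply_probability_floor(uniform_pwm(), 0.2)
        np.testing.assert_allclose(out.probs, 0.25)

    @pytest.mark.parametrize("floor", [0.25, 0.3, -0.01])
    def test_invalid_floor(self, floor):
        with pytest.raises(ValueError):
            motif.apply_probability_floor(uniform_pwm(), floor)


@settings(deadline=None, derandomize=True, max_examples=100)
@given(
    row=st.lists(st.floats(0.0, 1.0), min_size=4, max_size=4).filter(
        lambda r: sum(r) > 1e-6
    ),
    floor=st.floats(0.0, 0.249),
)
def test_floor_bounds_and_row_sums(row, floor):
    """After flooring, rows sum to 1 and no cell is below the effective
    lower bound floor / (1 + 4*floor)."""
    probs = np.array([row]) / sum(row)
    out = motif.apply_probability_floor(PWMatrix(probs=probs), floor)
    assert out.probs.sum() == pytest.approx(1.0, abs=1e-9)
    assert (out.probs >= floor / (1 + 4 * floor) - 1e-12).all()


class TestBestSite:
    def test_uniform_pwm_scores_zero(self, rng):
        pwm = uniform_pwm()
        for _ in range(5):
            score, _, _ = motif.score_best_site(pwm, random_seq(rng, 30))
            assert score == 0.0

    def test_closed_form_two_base_motif(self):
        pwm = sharp_pwm(L=2, p=0.97)
        expected = 2 * math.log2(0.97 / 0.25)
        score, pos, strand = motif.score_best_site(pwm, "CCAAC")
        assert score == pytest.approx(expected, rel=1e-12)
        assert (pos, strand) == (2, "+")
        # TT matches via the reverse-complement strand with the same score
        score_tt, _, strand_tt = motif.score_best_site(pwm, "CCTTC")
        assert score_tt == pytest.approx(expected, rel=1e-12)
        assert strand_tt == "-"

    def test_reverse_complement_invariance(self, rng):
        pwm = motif.apply_probability_floor(motif.p53_consensus_pwm(), 0.01)
        for _ in range(20):
            seq = random_seq(rng, 60)
            s1, _, _ = motif.score_best_site(pwm, seq)
            s2, _, _ = motif.score_best_site(pwm, motif.reverse_complement(seq))
            assert s1 == s2

    def test_n_windows_skipped(self):
        pwm = sharp_pwm(L=3, p=0.9)
        score, pos, _ = motif.score_best_site(pwm, "NNNAAAN")
        assert pos == 3  # only offset 3 is N-free
        assert math.isfinite(score)

    def test_all_windows_skipped(self):
        pwm = sharp_pwm(L=3)
        score, pos, _ = motif.score_best_site(pwm, "ANNANNA")
        assert score == float("-inf") and pos == -1

    def test_sequence_shorter_than_motif(self):
        with pytest.raises(ValueError, match="shorter"):
            motif.score_best_site(sharp_pwm(L=5), "ACG")

    def test_matches_enumeration_oracle(self, rng):
        pwm = motif.apply_probability_floor(
            PWMatrix(probs=rng.dirichlet(np.ones(4), size=6)), 0.01
        )
        for _ in range(50):
            seq = random_seq(rng, 40, with_n=True)
            got = motif.score_best_site(pwm, seq)
            want = brute_best_site(pwm.probs, pwm.background, seq)
            if math.isinf(want[0]):
                assert math.isinf(got[0])
            else:
                assert got[0] == pytest.approx(want[0], abs=1e-9)


class TestBackgroundRegions:
    def test_isolated_peak(self):
        peaks = PeakSet([GenomicInterval("chr1", 1000, 1500, "pk")])
        bg = motif.make_background_regions(peaks, 500)
        assert [(iv.start, iv.end, iv.name) for iv in bg] == [
            (500, 1000, "pk_bgL"),
            (1500, 2000, "pk_bgR"),
        ]

    def test_neighbor_blocks_left_flank(self):
        peaks = PeakSet(
            [
                GenomicInterval("chr1", 400, 900, "a"),
                GenomicInterval("chr1", 1000, 1500, "b"),
            ]
        )
        bg = motif.make_background_regions(peaks, 500)
        names = [iv.name for iv in bg]
        assert "b_bgL" not in names  # [500,1000) overlaps [400,900)
        assert "b_bgR" in names

    def test_genome_edge_dropped(self):
        peaks = PeakSet([GenomicInterval("chr1", 200, 700, "pk")])
        bg = motif.make_background_regions(peaks, 500)
        assert [iv.name for iv in bg] == ["pk_bgR"]

    def test_matches_bruteforce_and_never_overlaps_peaks(self, rng):
        for _ in range(20):
            peaks = random_intervals(rng, 25, max_width=1500, prefix="pk")
            bg = motif.make_background_regions(peaks, 500)
            got = sorted((iv.chrom, iv.start, iv.end) for iv in bg)
            assert got == brute_background_regions(peaks, 500)
            for b in bg:
                assert not any(b.overlaps(p) for p in peaks)


class TestSubsetCorrelation:
    def test_proportional_scores_give_r_one(self):
        # every sample is a rescaling of one latent profile, so any subset
        # mean is proportional to it and Pearson r is exactly 1
        base = np.array([1.0, 4.0, 2.0, 9.0])
        values = np.outer(base, [1.0, 2.0, 0.5])
        m = matrix(values)
        scores = pd.Series(base * 3.5, index=m.peak_ids)
        for k in (1, 2, 3):
            r = motif.subset_average_correlation(scores, m, k, seed=0)
            np.testing.assert_allclose(r, 1.0, atol=1e-12)

    def test_k_equals_n_single_subset(self, rng):
        m = matrix(rng.uniform(0, 10, size=(30, 5)))
        scores = pd.Series(rng.normal(size=30), index=m.peak_ids)
        r = motif.subset_average_correlation(scores, m, 5, seed=0)
        assert len(r) == 1
        assert r[0] == pytest.approx(
            two_pass_pearson(scores.to_numpy(), m.values.mean(axis=1)), abs=1e-12
        )

    def test_pearson_matches_two_pass_formula(self, rng):
        m = matrix(rng.uniform(0, 10, size=(50, 4)))
        scores = pd.Series(rng.normal(size=50), index=m.peak_ids)
        r = motif.subset_average_correlation(scores, m, 1, seed=0)
        for j in range(4):
            assert r[j] == pytest.approx(
                two_pass_pearson(scores.to_numpy(), m.values[:, j]), abs=1e-12
            )

    def test_sampling_cap(self, rng):
        m = matrix(rng.uniform(0, 10, size=(20, 10)))
        scores = pd.Series(rng.normal(size=20), index=m.peak_ids)
        r = motif.subset_average_correlation(scores, m, 5, max_combos=17, seed=3)
        assert len(r) == 17  # C(10,5)=252 capped to 17 distinct subsets

    def test_zero_variance_subset_is_nan(self, rng, caplog):
        values = rng.uniform(1, 5, size=(10, 3))
        values[:, 0] = 2.0  # constant sample
        m = matrix(values)
        scores = pd.Series(rng.normal(size=10), index=m.peak_ids)
        with caplog.at_level(logging.WARNING):
            r = motif.subset_average_correlation(scores, m, 1, seed=0)
        assert np.isnan(r[0]) and np.isfinite(r[1:]).all()

    def test_invalid_k(self):
        m = matrix(np.ones((5, 3)))
        with pytest.raises(ValueError):
            motif.subset_average_correlation(
                pd.Series(np.arange(5.0), index=m.peak_ids), m, 4
            )
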