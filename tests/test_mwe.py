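"""Minimum-width envelopes: greedy construction, tuning, and tests."""

import itertools

import numpy as np
import pytest

from dyadsync.exceptions import InputError
from dyadsync.mwe import (EnvelopeBand, bootstrap_mean_curves, greedy_mwe,
                          mwe_difference_test, naive_pointwise_band,
                          permutation_mwe_test, tune_k)


def exhaustive_min_area(curves, k):
    """Brute-force oracle: minimal envelope area over all k-subsets removed."""
    n = curves.shape[0]
    best = np.inf
    for removed in itertools.combinations(range(n), k):
        keep = np.ones(n, bool)
        keep[list(removed)] = False
        sub = curves[keep]
        best = min(best, float(np.sum(sub.max(0) - sub.min(0))))
    return best


class TestNaiveBand:
    def test_identical_curves_zero_width(self):
        c = np.tile(np.sin(np.linspace(0, 3, 21)), (30, 1))
        lo, hi = naive_pointwise_band(c)
        assert np.allclose(lo, hi)
        assert np.allclose(lo, c[0])

    def test_m_equals_one_reduces_to_percentile(self, rng):
        x = rng.standard_normal((100, 1))
        lo, hi = naive_pointwise_band(x, 0.05)
        assert lo[0] == pytest.approx(np.percentile(x, 2.5))
        assert hi[0] == pytest.approx(np.percentile(x, 97.5))

    def test_whole_curve_containment_below_pointwise(self, rng):
        """Pointwise coverage ~ 1-alpha, but whole-curve coverage is lower
        on a long grid of weakly dependent points."""
        train = rng.standard_normal((400, 21))
        fresh = rng.standard_normal((400, 21))
        lo, hi = naive_pointwise_band(train, 0.05)
        pointwise = np.mean((fresh >= lo) & (fresh <= hi))
        whole = np.mean(np.all((fresh >= lo) & (fresh <= hi), axis=1))
        assert pointwise == pytest.approx(0.95, abs=0.03)
        assert whole < 0.80


class TestGreedyMwe:
    def test_k0_is_minmax_and_contains_all(self, rng):
        c = rng.standard_normal((50, 21))
        band = greedy_mwe(c, 0)
        assert np.array_equal(band.lower, c.min(0))
        assert np.array_equal(band.upper, c.max(0))
        assert band.contains(c).all()

    def test_identical_curves_any_k_zero_width(self):
        c = np.tile(np.linspace(0, 1, 21), (10, 1))
        for k in (0, 3, 9):
            band = greedy_mwe(c, k)
            assert band.area == 0.0

    def test_k_out_of_range(self, rng):
        c = rng.standard_normal((5, 8))
        with pytest.raises(InputError):
            greedy_mwe(c, 5)

    @pytest.mark.parametrize("n", [5, 6, 8])
    def test_single_removal_is_exactly_optimal(self, n):
        # at k = 1 the greedy step IS the exhaustive search
        for seed in range(40):
            c = np.random.default_rng(seed).standard_normal((n, 3 + seed % 9))
            assert greedy_mwe(c, 1).area == pytest.approx(
                exhaustive_min_area(c, 1))

    def test_greedy_near_optimal_at_k2(self):
        """Stepwise removal is a heuristic at k >= 2: never below the
        optimum, exactly optimal on the large majority of small instances."""
        agree, total = 0, 60
        for seed in range(total):
            c = np.random.default_rng(seed).standard_normal((6, 21))
            greedy_area = greedy_mwe(c, 2).area
            opt = exhaustive_min_area(c, 2)
            assert greedy_area >= opt - 1e-12
            agree += greedy_area <= opt * (1 + 1e-9)
        assert agree / total >= 0.80

    def test_area_non_increasing_in_k(self, rng):
        c = rng.standard_normal((30, 15))
        areas = [greedy_mwe(c, k).area for k in range(0, 20)]
        assert all(a >= b - 1e-12 for a, b in zip(areas, areas[1:]))

    def test_translation_equivariance(self, rng):
        c = rng.standard_normal((20, 10))
        b0 = greedy_mwe(c, 3)
        b1 = greedy_mwe(c + 7.5, 3)
        assert np.allclose(b1.lower, b0.lower + 7.5)
        assert np.allclose(b1.upper, b0.upper + 7.5)


class TestTuneK:
    def test_validation_equals_training_full_coverage(self, rng):
        c = rng.standard_normal((60, 12))
        k, band = tune_k(c, c)
        assert band.contains(c).mean() >= 0.95

    def test_coverage_non_increasing_in_k(self, rng):
        tr = rng.standard_normal((80, 12))
        va = rng.standard_normal((80, 12))
        cov = [greedy_mwe(tr, k).contains(va).mean() for k in range(0, 40)]
        assert all(a >= b for a, b in zip(cov, cov[1:]))

    def test_tuned_band_meets_target_when_possible(self, rng):
        tr = rng.standard_normal((500, 21))
        va = rng.standard_normal((500, 21))
        k, band = tune_k(tr, va, target=0.90)
        assert band.contains(va).mean() >= 0.90
        assert k >= 0

    def test_under_coverage_flagged(self, rng):
        tr = rng.standard_normal((30, 10))
        va = rng.standard_normal((30, 10)) * 5.0      # much wider spread
        with pytest.warns(UserWarning, match="under-covers"):
            k, band = tune_k(tr, va)
        assert k == 0 and band.under_coverage


class TestDifferenceTest:
    def test_constant_offset_significant_everywhere(self):
        c = np.full((60, 21), 5.0)
        sig, mask, band = mwe_difference_test(c, rng=0)
        assert sig and mask.all()

    def test_symmetric_null_not_significant(self, rng):
        c = rng.standard_normal((400, 21)) * 3.0    # ample spread around 0
        sig, mask, band = mwe_difference_test(c, rng=1)
        assert not sig and not mask.any()

    def test_too_few_curves_refused(self, rng):
        with pytest.raises(InputError, match="bootstrap"):
            mwe_difference_test(rng.standard_normal((30, 21)))

    def test_bootstrap_mean_curves_shape_and_center(self, rng):
        d = rng.standard_normal((25, 21)) + 2.0
        boot = bootstrap_mean_curves(d, 500, rng)
        assert boot.shape == (500, 21)
        assert np.allclose(boot.mean(0), d.mean(0), atol=0.2)


class TestPermutationTest:
    def test_large_offset_significant(self, rng):
        a = rng.standard_normal((20, 21)) * 0.1 + 4.0
        b = rng.standard_normal((20, 21)) * 0.1
        sig, band = permutation_mwe_test(a, b, n_perm=500, rng=0)
        assert sig
        assert band.centering == "permutation"

    def test_null_calibration(self):
        """Exchangeable labels: rejection rate <= alpha (+ MC error).

        Curves are autocorrelated, like real event-locked means; the
        envelope's resolution requires the training split to be large
        relative to the number of effectively independent time points."""
        from scipy.ndimage import gaussian_filter1d
        rej = 0
        n_rep = 120
        for rep in range(n_rep):
            r = np.random.default_rng(rep)
            a = gaussian_filter1d(r.standard_normal((15, 21)), 2.0, axis=1)
            b = gaussian_filter1d(r.standard_normal((15, 21)), 2.0, axis=1)
            sig, _ = permutation_mwe_test(a, b, n_perm=1000, rng=r)
            rej += int(sig)
        assert rej / n_rep <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_small_n_perm_warns(self, rng):
        a, b = rng.standard_normal((2, 10, 5))
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_mwe_test(a, b, n_perm=100, rng=0)
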