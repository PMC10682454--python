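"""Peri-event timing, lag estimation, coupled pairs, ev/rev, persistence."""

import numpy as np
import pytest
from scipy.stats import hypergeom

from restplay import coupling as cp


class TestPeriEventAverage:
    def test_impulse_train_peaks_at_zero_lag(self, rng):
        fr = 19.0
        s = rng.normal(0, 0.01, 4000)
        events = [50.0, 90.0, 130.0]
        for t in events:
            s[int(t * fr)] += 5.0
        pea = cp.peri_event_average(s, events, fr, window_s=1.0)
        assert pea.lags_s[np.argmax(pea.mean_z)] == pytest.approx(0.0)
        assert pea.n_events == 3

    def test_single_event_average_is_that_window(self, rng):
        fr = 19.0
        s = rng.normal(size=2000)
        pea = cp.peri_event_average(s, [50.0], fr, window_s=1.0)
        z = (s - s.mean()) / s.std()
        f = int(50.0 * fr)
        assert np.allclose(pea.mean_z, z[f - 19: f + 20])

    def test_events_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cp.peri_event_average(np.random.default_rng(0).normal(size=100),
                                  [500.0], 19.0)


class TestLagEstimation:
    def test_identical_series_lag_zero(self, rng):
        a = rng.normal(size=4000)
        est = cp.xcorr_gaussian_lag(a, a, 19.0)
        assert abs(est.lag_s) < 1 / 19.0

    @pytest.mark.parametrize("shift", [2, 5])
    def test_planted_delay_recovered(self, rng, shift):
        fr = 19.0
        a = np.convolve(rng.normal(size=4000), np.hanning(5), "same")
        b = np.roll(a, shift)
        est = cp.xcorr_gaussian_lag(a, b, fr)
        assert est.lag_s == pytest.approx(shift / fr, abs=1 / fr)

    def test_antisymmetry_under_argument_swap(self, rng):
        a = np.convolve(rng.normal(size=4000), np.hanning(5), "same")
        b = np.roll(a, 3)
        ab = cp.xcorr_gaussian_lag(a, b, 19.0)
        ba = cp.xcorr_gaussian_lag(b, a, 19.0)
        assert ab.lag_s == pytest.approx(-ba.lag_s, abs=2 / 19.0)


class TestOnsetCrossCorrelogram:
    def test_identical_trains_peak_at_zero(self):
        on = np.arange(1.0, 60.0, 2.0)
        centers, counts, lo, hi = cp.onset_crosscorrelogram(
            on, on, bin_ms=100, n_boot=100, seed=0)
        assert centers[np.argmax(counts)] == pytest.approx(0.05, abs=0.1)

    def test_planted_offset_is_modal_bin(self):
        on = np.arange(1.0, 120.0, 2.0)
        centers, counts, _, _ = cp.onset_crosscorrelogram(
            on + 0.35, on, bin_ms=100, n_boot=100, seed=0)
        assert abs(centers[np.argmax(counts)] - 0.35) <= 0.05

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            cp.onset_crosscorrelogram([1.0], [2.0, 3.0, 4.0, 5.0, 6.0])


class TestCoupledPairs:
    def test_identical_series_coupled_at_zero_lag(self, rng):
        fr = 19.0
        s = np.convolve(rng.normal(size=4000), np.hanning(4), "same")
        pairs = cp.find_coupled_pairs(s, s, fr, n_null=200, seed=0)
        assert pairs[0].coupled
        assert abs(pairs[0].lag_s) < 0.1

    def test_planted_co_reactivation_lag(self, rng):
        fr = 19.0
        T = 8000
        base = np.zeros(T)
        events = rng.choice(np.arange(100, T - 100), 60, replace=False)
        for t in events:
            base[t: t + 3] += [0.5, 1.0, 0.4]
        a = base + 0.05 * rng.normal(size=T)
        b = np.roll(base, 2) + 0.05 * rng.normal(size=T)
        pairs = cp.find_coupled_pairs(a, b, fr, n_null=200, seed=0)
        assert pairs[0].coupled
        assert pairs[0].lag_s == pytest.approx(2 / fr, abs=1.5 / fr)

    def test_null_calibration_on_independent_pairs(self, rng):
        fr = 19.0
        n_pairs = 60
        flags = []
        for i in range(n_pairs):
            a = np.convolve(rng.normal(size=2500), np.hanning(4), "same")
            b = np.convolve(rng.normal(size=2500), np.hanning(4), "same")
            flags.append(cp.find_coupled_pairs(
                a, b, fr, n_null=200, seed=i)[0].coupled)
        # false-positive rate ~ alpha = 0.05 (binomial 99% upper bound)
        assert np.mean(flags) <= 0.05 + 2.6 * np.sqrt(0.05 * 0.95 / n_pairs)


class TestFeatureSimilarity:
    def test_identity_and_negation(self, rng):
        f = rng.normal(size=50)
        r, z = cp.feature_similarity(f, f)
        assert r == pytest.approx(1.0)
        r2, _ = cp.feature_similarity(f, -f)
        assert r2 == pytest.approx(-1.0)

    def test_fisher_transform_consistency(self, rng):
        a, b = rng.normal(size=(2, 50))
        r, z = cp.feature_similarity(a, b)
        assert z == pytest.approx(np.arctanh(r))

    def test_flat_feature_rejected(self):
        with pytest.raises(ValueError):
            cp.feature_similarity(np.ones(50), np.arange(50.0))


class TestSwrAssociation:
    def test_no_swrs_gives_zero(self):
        assert cp.swr_association_fraction([1.0, 2.0], []) == 0.0

    def test_all_events_near_swrs(self):
        swr = [10.0, 20.0, 30.0]
        ev = [10.1, 20.1, 30.1]
        assert cp.swr_association_fraction(ev, swr, 0.5) == 100.0

    def test_poisson_closed_form(self, rng):
        lam, w, dur = 0.2, 0.5, 5000.0
        swr = np.sort(rng.uniform(0, dur, rng.poisson(lam * dur)))
        ev = rng.uniform(0, dur, 2000)
        expect = 100 * (1 - np.exp(-2 * lam * w))
        got = cp.swr_association_fraction(ev, swr, w)
        assert got == pytest.approx(expect, abs=5.0)


class TestExplainedVariance:
    def _blocks(self, rng, re_express=True):
        T, n = 3000, 30
        sources = rng.normal(size=(T, 3))
        mix = rng.normal(size=(3, n)) * 0.7
        run = sources @ mix + rng.normal(size=(T, n))
        if re_express:
            rest2 = rng.normal(size=(T, 3)) @ mix + rng.normal(size=(T, n))
        else:
            rest2 = rng.normal(size=(T, n))
        rest1 = rng.normal(size=(T, n))
        return rest1, run, rest2

    def test_reexpression_drives_ev_above_rev(self, rng):
        rest1, run, rest2 = self._blocks(rng)
        ev, rev = cp.explained_variance(rest1, run, rest2)
        assert 0 <= rev < ev <= 100

    def test_swapping_rest_blocks_swaps_ev_rev(self, rng):
        rest1, run, rest2 = self._blocks(rng)
        ev, rev = cp.explained_variance(rest1, run, rest2)
        ev2, rev2 = cp.explained_variance(rest2, run, rest1)
        assert ev == pytest.approx(rev2) and rev == pytest.approx(ev2)

    def test_all_noise_gives_small_symmetric_values(self, rng):
        ev, rev = cp.explained_variance(rng.normal(size=(3000, 30)),
                                        rng.normal(size=(3000, 30)),
                                        rng.normal(size=(3000, 30)))
        assert ev < 5 and rev < 5

    def test_too_few_neurons_rejected(self, rng):
        with pytest.raises(ValueError):
            cp.explained_variance(*[rng.normal(size=(100, 3))] * 3)


class TestPersistence:
    def test_jaccard_examples(self):
        assert cp.jaccard_persistence(range(1, 7), range(4, 10)) \
            == pytest.approx(1 / 3)
        assert cp.jaccard_persistence({1, 2}, {1, 2}) == 1.0
        assert cp.jaccard_persistence({1, 2}, {3, 4}) == 0.0
        with pytest.raises(ValueError):
            cp.jaccard_persistence([], [])

    def test_max_jaccard_selects_best_partner(self):
        assert cp.max_jaccard([1, 2, 3], [[4, 5], [2, 3, 9]]) \
            == pytest.approx(0.5)
        assert cp.max_jaccard([1, 2], []) == 0.0

    def test_fisher_tail_matches_overlap_distribution(self):
        """One-sided Fisher p equals the exact tail of the random-overlap
        (hypergeometric) null for small universes."""
        for (O, A, B, N) in [(3, 4, 5, 12), (2, 6, 6, 15), (0, 3, 4, 10)]:
            p, _ = cp.persistence_significance(O, A, B, N, alpha=0.5)
            exact = hypergeom.sf(O - 1, N, A, B)
            assert p == pytest.approx(exact, rel=1e-9)

    def test_complete_overlap_small_universe_significant(self):
        p, sig = cp.persistence_significance(6, 6, 6, 40, alpha=0.001)
        assert sig and p < 1e-5

    def test_zero_overlap_not_significant(self):
        p, sig = cp.persistence_significance(0, 5, 5, 100)
        assert not sig and p >= 0.001

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            cp.persistence_significance(5, 4, 6, 20)


def test_galvo_dwell_uncertainty_bound():
    assert cp.galvo_dwell_ci_ms(50.0) == pytest.approx(50 / 3)
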