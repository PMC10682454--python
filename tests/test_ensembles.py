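"""Ensemble detection, segment extraction, labels, and enrichment."""

import math

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from restplay.ensembles import (EnsembleDetector, classify_ensemble,
                                correlation_distance, correlation_to_distance,
                                detect_ensembles, encoding_bias,
                                extract_trajectory_segments,
                                hypergeometric_enrichment, label_ensembles,
                                segment_length_cm)
from restplay.spatial import PlaceField, SpatialCellResult, TuningCurve


def _spatial_stub(n, spatial_ids):
    f = PlaceField(center_bin=0, width_bins=5, scale=3, bins=(0, 1))
    return [SpatialCellResult(i, 1.0, 0.01 if i in spatial_ids else 0.5,
                              [f] if i in spatial_ids else [])
            for i in range(n)]


def _curve(values):
    v = np.asarray(values, dtype=float)
    return TuningCurve(values=v, occupancy=np.full(len(v), 1 / len(v)),
                       overall_mean=float(v.mean()),
                       empty=np.zeros(len(v), bool))


def _bump(center, sigma, n=50):
    x = np.arange(n)
    d = np.minimum(np.abs(x - center), n - np.abs(x - center))
    return np.exp(-0.5 * (d / sigma) ** 2)


class TestCorrelationDistance:
    def test_identical_and_anticorrelated_traces(self):
        t = np.sin(np.linspace(0, 40 * np.pi, 4000))
        X = np.column_stack([t, t, -t])
        dm = correlation_distance(X, sigma_ms=0.01)
        assert dm.d[0, 1] == pytest.approx(0.0, abs=1e-10)
        assert dm.d[0, 2] == pytest.approx(2.0, abs=1e-10)
        assert np.allclose(dm.d, dm.d.T)
        assert np.all(np.diag(dm.d) == 0)

    def test_independent_noise_is_near_unit_distance(self, rng):
        X = rng.normal(size=(10_000, 4))
        dm = correlation_distance(X, sigma_ms=0.01)
        off = dm.d[np.triu_indices(4, 1)]
        assert np.all(np.abs(off - 1.0) < 0.05)

    def test_constant_trace_flagged_invalid(self):
        X = np.column_stack([np.ones(500), np.random.default_rng(0)
                             .normal(size=500), np.zeros(500)])
        dm = correlation_distance(X, sigma_ms=0.01)
        assert list(dm.valid) == [False, True, False]

    def test_distance_transform_is_one_minus_r(self):
        assert correlation_to_distance(0.25) == pytest.approx(0.75)
        assert correlation_to_distance(-1.0) == pytest.approx(2.0)


def _burst_population(rng, groups, n_noise, T=6000, n_events=25):
    """Synchronous transient bursts for each planted group."""
    n = sum(groups) + n_noise
    X = np.clip(rng.normal(0, 0.05, (T, n)), 0, None)
    start = 0
    kernel = np.array([0.4, 1.0, 0.6, 0.2])
    labels = np.full(n, -1)
    for g, size in enumerate(groups):
        ids = np.arange(start, start + size)
        labels[ids] = g
        for t in rng.choice(np.arange(50, T - 50), size=n_events,
                            replace=False):
            amp = rng.uniform(0.8, 1.2, size)
            X[t:t + 4, ids] += kernel[:, None] * amp[None, :] * 3
        start += size
    return X, labels


class TestDetectEnsembles:
    def test_planted_groups_recovered(self, rng):
        X, labels = _burst_population(rng, [6, 8, 10], n_noise=20)
        det = EnsembleDetector().fit(X)
        assert adjusted_rand_score(labels, det.labels_) >= 0.9

    def test_group_of_four_not_reported(self, rng):
        X, _ = _burst_population(rng, [4], n_noise=20)
        det = EnsembleDetector().fit(X)
        assert det.ensembles_ == []

    def test_independent_population_yields_nothing(self, rng):
        X = np.clip(rng.normal(0, 0.1, (6000, 30)), 0, None)
        assert EnsembleDetector().fit(X).ensembles_ == []

    def test_invariant_to_neuron_permutation(self, rng):
        X, _ = _burst_population(rng, [6, 7], n_noise=10)
        perm = rng.permutation(X.shape[1])
        base = EnsembleDetector().fit(X).ensembles_
        shuf = EnsembleDetector().fit(X[:, perm]).ensembles_
        mapped = sorted(sorted(int(perm[i]) for i in e.members)
                        for e in shuf)
        assert mapped == sorted(e.members for e in base)

    def test_within_ensemble_mean_correlation_exceeds_cutoff(self, rng):
        X, _ = _burst_population(rng, [6, 8], n_noise=15)
        dm = correlation_distance(X)
        for e in detect_ensembles(dm):
            r = [1 - dm.d[i, j] for i in e.members for j in e.members
                 if i < j]
            assert np.mean(r) >= 0.25


class TestSegments:
    def test_identical_narrow_bumps_give_one_short_segment(self):
        curves = [_curve(_bump(10, 1.5)) for _ in range(5)]
        segs = extract_trajectory_segments(
            list(range(5)), _spatial_stub(5, set(range(5))), curves)
        assert len(segs) == 1
        assert segment_length_cm(segs[0], 150) < 30

    def test_tiling_members_span_their_range(self):
        centers = np.linspace(40 / 3, 80 / 3, 6)  # 40-80 cm in bins
        curves = [_curve(_bump(c, 2.0)) for c in centers]
        segs = extract_trajectory_segments(
            list(range(6)), _spatial_stub(6, set(range(6))), curves)
        assert len(segs) == 1
        start, end, wrapped = segs[0]
        assert not wrapped
        assert start < 42 and end > 78

    def test_two_spatial_members_yield_nothing(self):
        curves = [_curve(_bump(10, 2.0)) for _ in range(5)]
        segs = extract_trajectory_segments(
            list(range(5)), _spatial_stub(5, {0, 1}), curves)
        assert segs == []

    def test_wrap_across_reward_line(self):
        curves = [_curve(_bump(c % 50, 1.5)) for c in (47, 49, 1, 3)]
        segs = extract_trajectory_segments(
            list(range(4)), _spatial_stub(4, set(range(4))), curves)
        assert len(segs) == 1
        assert segs[0][2]  # wrapped flag


class TestClassification:
    def test_short_segment_on_cue_is_cue(self):
        assert classify_ensemble([(22.0, 38.0, False)], [30.0]) == "cue"

    def test_long_segment_is_trajectory(self):
        assert classify_ensemble([(40.0, 80.0, False)], [60.0]) == "trajectory"

    def test_no_segments_is_none(self):
        assert classify_ensemble([], [30.0]) == "none"

    def test_cue_beats_additional_long_segments(self):
        segs = [(40.0, 90.0, False), (25.0, 35.0, False)]
        assert classify_ensemble(segs, [30.0]) == "cue"

    def test_short_segment_missing_all_cues_is_trajectory(self):
        assert classify_ensemble([(60.0, 75.0, False)], [30.0]) == "trajectory"


class TestEncodingBias:
    def _positions(self):
        return np.tile(np.linspace(0, 150, 250, endpoint=False), 12)

    def test_place_cell_away_from_cues_favours_gaussian_model(self, rng):
        pos = self._positions()
        act = 2 * np.exp(-0.5 * ((pos - 75) / 6) ** 2) \
            + rng.normal(0, 0.02, len(pos)).clip(0)
        eb = encoding_bias(act, pos, cue_centers_cm=[20, 120])
        assert eb.ratio < 0

    def test_cell_firing_at_every_cue_favours_cue_model(self, rng):
        pos = self._positions()
        cues = [20, 55, 100, 120]
        act = sum(np.exp(-0.5 * ((pos - c) / 3) ** 2) for c in cues) \
            + rng.normal(0, 0.02, len(pos)).clip(0)
        eb = encoding_bias(act, pos, cue_centers_cm=cues)
        assert eb.ratio > 0

    def test_silent_neuron_rejected(self):
        with pytest.raises(ValueError):
            encoding_bias(np.zeros(3000), self._positions(), [20.0])


class TestHypergeometric:
    @staticmethod
    def _oracle(k, m, K, N):
        """Exact upper tail by direct summation of the draw distribution."""
        total = math.comb(N, m)
        return sum(math.comb(K, i) * math.comb(N - K, m - i)
                   for i in range(k, min(m, K) + 1)) / total

    @pytest.mark.parametrize("k,m,K,N", [
        (5, 5, 5, 10), (0, 5, 5, 10), (2, 6, 5, 15), (3, 5, 8, 20),
    ])
    def test_matches_exact_enumeration(self, k, m, K, N):
        assert hypergeometric_enrichment(k, m, K, N) == pytest.approx(
            self._oracle(k, m, K, N), abs=1e-12)

    def test_all_spatial_draw_probability(self):
        assert hypergeometric_enrichment(5, 5, 5, 10) == pytest.approx(
            1 / 252, rel=1e-9)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(6, 5, 5, 10)


def test_labels_partition_detected_ensembles(default_session,
                                             default_spatial):
    """Every detected REST2 ensemble receives exactly one label and the
    planted cue/trajectory identities are recovered."""
    from restplay.spatial import compute_tuning_curve
    bundle, truth = default_session
    det = EnsembleDetector().fit(bundle.rest2,
                                 movement_mask=bundle.rest2_movement_mask)
    tuning = [compute_tuning_curve(bundle.run[:, i], bundle.position_cm)
              for i in range(bundle.run.shape[1])]
    label_ensembles(det.ensembles_, default_spatial.results_, tuning,
                    bundle.meta.cue_centers_cm)
    assert all(e.label in ("cue", "trajectory", "none")
               for e in det.ensembles_)
    by_members = {tuple(m): lab for m, lab in
                  zip(truth.ensemble_members, truth.ensemble_labels)}
    hits = sum(by_members.get(tuple(e.members)) == e.label
               for e in det.ensembles_)
    assert hits >= 0.9 * len(truth.ensemble_members)
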