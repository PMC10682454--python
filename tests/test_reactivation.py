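"""Seeded PCA-ICA: basis algebra, component selection, event detection."""

import numpy as np
import pytest

from restplay.reactivation import (ReactivationModel, build_seed_basis,
                                   denoise_residual,
                                   detect_reactivation_events,
                                   fit_reconstruction_ica,
                                   reactivation_strength, select_components,
                                   standardize)


class TestSeedBasis:
    def test_entries_are_inverse_sqrt_sizes(self):
        sb = build_seed_basis([[0, 1, 2, 3], list(range(4, 13))], 20)
        assert sb.W[0, 0] == pytest.approx(0.5)
        assert sb.W[4, 1] == pytest.approx(1 / 3)
        assert np.allclose(sb.W.T @ sb.W, np.eye(2), atol=1e-10)

    def test_single_full_ensemble(self):
        sb = build_seed_basis([list(range(9))], 9)
        assert np.allclose(sb.W[:, 0], 1 / 3)

    def test_overlapping_members_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            build_seed_basis([[0, 1, 2], [2, 3, 4]], 10)


class TestDenoise:
    def test_residual_orthogonal_to_seeds(self, rng):
        W = build_seed_basis([[0, 1, 2], [5, 6, 7, 8]], 12).W
        X = rng.normal(size=(500, 12))
        Xh = denoise_residual(X, W)
        assert np.abs(Xh @ W).max() < 1e-8

    def test_pythagoras(self, rng):
        W = build_seed_basis([[0, 1, 2], [5, 6, 7, 8]], 12).W
        X = rng.normal(size=(500, 12))
        Xh = denoise_residual(X, W)
        proj = X @ W @ W.T
        lhs = np.sum(X ** 2)
        rhs = np.sum(proj ** 2) + np.sum(Xh ** 2)
        assert lhs == pytest.approx(rhs, rel=1e-6)

    def test_in_span_maps_to_zero(self, rng):
        W = build_seed_basis([[0, 1], [2, 3, 4]], 5).W
        X = rng.normal(size=(100, 2)) @ W.T
        assert np.abs(denoise_residual(X, W)).max() < 1e-10


class TestComponentSelection:
    def test_marchenko_pastur_bound_closed_form(self, rng):
        sel = select_components(rng.normal(size=(10_000, 100)))
        assert sel.lambda_plus == pytest.approx((1 + 0.1) ** 2)

    def test_planted_global_component_is_kept(self, rng):
        T, N = 5000, 50
        shared = rng.normal(size=T)
        X = rng.normal(size=(T, N)) + 0.8 * shared[:, None]
        sel = select_components(X)
        assert sel.kept.shape[1] == 1

    def test_kept_eigvals_exceed_bound(self, rng):
        X = rng.normal(size=(2000, 30)) \
            + 0.9 * rng.normal(size=(2000, 1))
        sel = select_components(X)
        assert np.all(sel.eigvals[: sel.kept.shape[1]] > sel.lambda_plus)


class TestReconstructionIca:
    def _mixed_sources(self, seed, T=8000, n=30, k=3):
        rng = np.random.default_rng(seed)
        S = (rng.random((T, k)) < 0.02) * rng.laplace(0, 1, (T, k))
        S = (S - S.mean(0)) / S.std(0)
        A = np.linalg.qr(rng.normal(size=(n, k)))[0]
        X = S @ A.T + 0.02 * rng.normal(size=(T, n))
        R = np.linalg.qr(rng.normal(size=(k, k)))[0]
        return X, A @ R, S

    def test_objective_at_identity_is_pure_penalty(self, rng):
        X, Q, _ = self._mixed_sources(0)
        model = fit_reconstruction_ica(X, Q, max_iter=0)
        # W = I is orthogonal, so the reconstruction term vanishes and
        # the initial objective equals the contrast penalty
        Xp = X @ Q
        Xp = Xp / np.sqrt(np.mean(Xp ** 2))
        penalty = np.sum(0.5 * np.log(np.cosh(2 * Xp))) / Xp.shape[0]
        assert model.objective_trace[0] == pytest.approx(penalty, rel=1e-10)

    def test_objective_trace_non_increasing(self):
        X, Q, _ = self._mixed_sources(1)
        model = fit_reconstruction_ica(X, Q)
        trace = np.array(model.objective_trace)
        assert np.all(np.diff(trace) <= 1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recovers_orthogonally_mixed_sparse_sources(self, seed):
        X, Q, S = self._mixed_sources(seed)
        model = fit_reconstruction_ica(X, Q, n_ensembles=3)
        rec = X @ model.components
        cc = np.abs(np.corrcoef(rec.T, S.T)[:3, 3:])
        assert cc.max(axis=1).min() >= 0.9

    def test_components_are_unit_norm_sign_fixed(self):
        X, Q, _ = self._mixed_sources(2)
        model = fit_reconstruction_ica(X, Q, n_ensembles=3)
        norms = np.linalg.norm(model.components, axis=0)
        assert np.allclose(norms, 1.0)
        for j in range(3):
            i = np.argmax(np.abs(model.components[:, j]))
            assert model.components[i, j] > 0


class TestStrengthAndEvents:
    def test_zero_activity_zero_strength(self):
        comps = np.zeros((10, 2))
        comps[0, 0] = comps[1, 1] = 1.0
        assert np.all(reactivation_strength(np.zeros((50, 10)), comps) == 0)

    def test_strength_ignores_zero_weight_neurons(self, rng):
        comps = np.zeros((10, 1))
        comps[:3, 0] = 1 / np.sqrt(3)
        X = rng.normal(size=(200, 10))
        Y = X.copy()
        Y[:, 3:] = rng.normal(size=(200, 7))
        assert np.allclose(reactivation_strength(X, comps),
                           reactivation_strength(Y, comps))

    def test_flat_series_has_no_events(self):
        assert detect_reactivation_events(np.ones(2000), 19.0) == []

    def test_single_strong_bump_is_one_event(self, rng):
        # uniform baseline: bounded at ~1.73 SD, so the only supra-3SD
        # excursion is the planted bump
        s = rng.uniform(-1, 1, 4000)
        s[2000:2004] += np.array([3.0, 10.0, 6.0, 2.0]) * s.std()
        events = detect_reactivation_events(s, 19.0)
        assert len(events) == 1
        ev = events[0]
        assert ev.onset_s < ev.peak_s <= ev.offset_s
        assert abs(ev.peak_s - 2000 / 19.0) < 0.3
        assert ev.peak_strength > 3

    def test_weak_bump_below_threshold_ignored(self, rng):
        s = rng.uniform(-1, 1, 4000)
        s[2000] += 2 * s.std()
        assert detect_reactivation_events(s, 19.0) == []


class TestEndToEnd:
    def test_planted_events_recovered_with_high_precision(
            self, default_session):
        bundle, truth = default_session
        model = ReactivationModel().fit(
            bundle.rest2, member_sets=truth.ensemble_members,
            movement_mask=bundle.rest2_movement_mask)
        events = model.detect_events(bundle.rest2)
        hits = total = matched = 0
        for m, times in enumerate(truth.reactivation_times_s["rest2"]):
            dets = [e for e in events if e.ensemble_id == m]
            for t in times:
                total += 1
                hits += any(abs(e.peak_s - t) <= 0.3 for e in dets)
            matched += sum(any(abs(e.peak_s - t) <= 0.3 for t in times)
                           for e in dets)
        assert hits / total >= 0.9
        assert matched / len(events) >= 0.9

    def test_ica_refinement_does_not_lose_planted_events(
            self, default_session):
        bundle, truth = default_session

        def hit_count(use_ica):
            model = ReactivationModel(use_ica=use_ica).fit(
                bundle.rest2, member_sets=truth.ensemble_members,
                movement_mask=bundle.rest2_movement_mask)
            events = model.detect_events(bundle.rest2)
            hits = 0
            for m, times in enumerate(truth.reactivation_times_s["rest2"]):
                dets = [e for e in events if e.ensemble_id == m]
                hits += sum(any(abs(e.peak_s - t) <= 0.3 for e in dets)
                            for t in times)
            return hits

        assert hit_count(True) >= hit_count(False)

    def test_basis_orthonormal_and_strength_standardized(
            self, default_session):
        bundle, truth = default_session
        model = ReactivationModel().fit(
            bundle.rest2, member_sets=truth.ensemble_members,
            movement_mask=bundle.rest2_movement_mask)
        Wp = model.W_prime_
        assert np.allclose(Wp.T @ Wp, np.eye(Wp.shape[1]), atol=1e-8)
        Z, _, _ = standardize(
            bundle.rest2[~bundle.rest2_movement_mask], model.mean_,
            model.sd_)
        assert abs(Z.mean()) < 0.05
        assert abs(Z.std() - 1.0) < 0.25

    def test_run_features_follow_planted_segments(self, default_session):
        bundle, truth = default_session
        model = ReactivationModel().fit(
            bundle.rest2, member_sets=truth.ensemble_members,
            movement_mask=bundle.rest2_movement_mask)
        feats = model.run_features(bundle.run, bundle.position_cm)
        for m, (lo, hi) in enumerate(truth.ensemble_segments_cm):
            f = feats[m] - feats[m].min()
            bins = np.arange(50) * 3.0 + 1.5
            if lo <= hi:
                inside = (bins >= lo - 3) & (bins <= hi + 3)
            else:
                inside = (bins >= lo - 3) | (bins <= hi + 3)
            assert f[inside].mean() > f[~inside].mean()
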