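"""Discriminant Laplacian-eigenmap fit, V scoring and the stability filter."""

import numpy as np
import pytest
from scipy import stats

from hsm.data import CohortDesign, ExpressionMatrix, zscore_normalize
from hsm.manifold import (
    DegenerateManifoldError,
    HealthManifold,
    ManifoldResults,
    between_scatter,
    combine_v_axes,
    cv_feature_selection,
    fit_manifold,
    laplacian,
    sample_adjacency,
    trace_ratio_objective,
)
from hsm.simulate import SimConfig, simulate_health_trajectory, trajectory_design

from conftest import make_matrix


def _em(values, prefix="s"):
    return make_matrix(values, prefix=prefix)


class TestSampleAdjacency:
    def test_identical_rows_have_weight_one(self):
        X = _em([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [0.0, 5.0, 1.0]])
        W = sample_adjacency(X)
        assert W[0, 1] == pytest.approx(1.0)
        assert np.all(np.diag(W) == 0)

    def test_negative_correlation_clamped_to_zero(self):
        X = _em([[1.0, 2.0, 3.0], [-1.0, -2.0, -3.0]])
        assert sample_adjacency(X)[0, 1] == 0.0
        assert sample_adjacency(X, mode="abs")[0, 1] == pytest.approx(1.0)

    def test_matches_pairwise_pcc_oracle(self, rng):
        values = rng.standard_normal((3, 5))
        W = sample_adjacency(values)
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                r = stats.pearsonr(values[i], values[j]).statistic
                assert W[i, j] == pytest.approx(max(r, 0.0), abs=1e-12)

    def test_constant_row_defined_as_zero(self):
        X = _em([[1.0, 1.0, 1.0], [0.0, 2.0, 1.0], [3.0, 1.0, 0.0]])
        W = sample_adjacency(X)
        assert np.all(W[0] == 0.0)


class TestLaplacian:
    def test_zero_weights_give_zero_laplacian(self):
        L, D = laplacian(np.zeros((3, 3)))
        assert np.all(L == 0) and np.all(D == 0)

    def test_complete_graph_spectrum(self):
        W = np.ones((3, 3)) - np.eye(3)
        L, D = laplacian(W)
        np.testing.assert_allclose(np.diag(D), 2.0)
        np.testing.assert_allclose(np.sort(np.linalg.eigvalsh(L)), [0.0, 3.0, 3.0],
                                   atol=1e-12)

    def test_psd_and_null_vector(self, rng):
        W = sample_adjacency(rng.standard_normal((6, 8)))
        L, _ = laplacian(W)
        np.testing.assert_allclose(L @ np.ones(6), 0.0, atol=1e-12)
        assert np.linalg.eigvalsh(L).min() >= -1e-10

    def test_asymmetric_rejected(self):
        W = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            laplacian(W)


class TestBetweenScatter:
    def test_identical_means_give_zero(self):
        XH = _em([[1.0, 2.0], [3.0, 4.0]], "h")
        XD = _em([[0.0, 3.0], [4.0, 3.0]], "d")
        np.testing.assert_allclose(between_scatter(XH, XD), 0.0, atol=1e-12)

    def test_hand_outer_product(self):
        XH = _em([[0.0, 0.0]], "h")
        XD = _em([[1.0, 2.0]], "d")
        B = between_scatter(XH, XD)
        np.testing.assert_allclose(B, [[1.0, 2.0], [2.0, 4.0]])
        assert np.trace(B) == pytest.approx(5.0)

    def test_rank_at_most_one(self, rng):
        B = between_scatter(rng.standard_normal((4, 6)), rng.standard_normal((5, 6)))
        ev = np.sort(np.linalg.eigvalsh(B))[::-1]
        assert ev[1] < 1e-10 * max(ev[0], 1.0)

    def test_feature_mismatch_rejected(self):
        XH = make_matrix([[1.0, 2.0]], fprefix="a")
        XD = make_matrix([[1.0, 2.0]], fprefix="b")
        with pytest.raises(ValueError):
            between_scatter(XH, XD)


class TestFit:
    def test_signal_feature_dominates_loading(self):
        r = np.random.default_rng(3)
        VH = r.standard_normal((20, 5))
        VD = r.standard_normal((20, 5))
        VD[:, 0] += 6.0
        ids = [f"h{i}" for i in range(20)] + [f"d{i}" for i in range(20)]
        X = zscore_normalize(
            ExpressionMatrix(np.vstack([VH, VD]), ids, [f"g{j}" for j in range(5)])
        )
        res = HealthManifold(X, CohortDesign(ids[:20], ids[20:])).fit()
        assert abs(res.C[0, 0]) > 0.9

    def test_brute_force_rayleigh_oracle_small_p(self, rng):
        """For p=3 the fitted direction must match the arg-max of the
        trace-ratio objective found by dense random search."""
        for _ in range(5):
            VH = rng.standard_normal((5, 3))
            VD = rng.standard_normal((5, 3)) + rng.normal(0, 1.5, 3)
            XH = _em(VH, "h")
            XD = _em(VD, "d")
            res = fit_manifold(XH, XD, epsilon=1e-10)
            Xall = np.vstack([VH, VD])
            L, _ = laplacian(sample_adjacency(Xall))
            Sigma = Xall.T @ L @ Xall + res.epsilon * np.eye(3)
            B = between_scatter(XH, XD)
            c = res.C[:, 0]
            f_fit = trace_ratio_objective(c, B, Sigma)
            R = rng.standard_normal((10_000, 3))
            R /= np.linalg.norm(R, axis=1, keepdims=True)
            f_rand = np.einsum("ij,jk,ik->i", R, B, R) / np.einsum(
                "ij,jk,ik->i", R, Sigma, R
            )
            best = R[np.argmax(f_rand)]
            assert f_rand.max() <= f_fit * (1 + 1e-6)
            # 1e4 random directions resolve the 2-sphere to ~pi/sqrt(N) rad
            angle = np.arccos(min(1.0, abs(best @ c)))
            assert angle < 5e-2

    def test_identical_groups_flagged_degenerate(self, rng):
        V = rng.standard_normal((4, 5))
        XH = _em(V, "h")
        XD = _em(V, "d")
        with pytest.raises(DegenerateManifoldError):
            fit_manifold(XH, XD)

    def test_d_larger_than_p_rejected(self, separated_cohort):
        X, design = separated_cohort
        with pytest.raises(ValueError):
            HealthManifold(X, design, d=99).fit()

    def test_unit_norm_columns_and_extra_dims(self, separated_cohort):
        X, design = separated_cohort
        res = HealthManifold(X, design, d=3).fit()
        np.testing.assert_allclose(np.linalg.norm(res.C, axis=0), 1.0, atol=1e-10)
        assert res.C.shape == (5, 3)


class TestProjection:
    def test_training_scores_reproduce_bit_identically(self, separated_cohort):
        X, design = separated_cohort
        res = HealthManifold(X, design).fit()
        v1 = res.predict(X)
        v2 = res.predict(X)
        np.testing.assert_array_equal(v1.v_neg_scaled, v2.v_neg_scaled)

    def test_groups_separate_on_fixture(self, separated_cohort):
        X, design = separated_cohort
        res = HealthManifold(X, design).fit()
        vs = res.predict(X)
        bg = vs.v_raw[:8]
        tg = vs.v_raw[8:]
        assert stats.ttest_ind(bg, tg).pvalue < 0.01

    def test_feature_permutation_invariance(self, separated_cohort):
        X, design = separated_cohort
        res = HealthManifold(X, design).fit()
        perm = [3, 0, 4, 1, 2]
        Xp = ExpressionMatrix(
            X.values[:, perm], X.sample_ids, [X.feature_ids[j] for j in perm]
        )
        np.testing.assert_allclose(
            res.predict(Xp).v_neg_scaled, res.predict(X).v_neg_scaled, atol=1e-12
        )

    def test_missing_feature_named_in_error(self, separated_cohort):
        X, design = separated_cohort
        res = HealthManifold(X, design).fit()
        Xs = ExpressionMatrix(X.values[:, :4], X.sample_ids, X.feature_ids[:4])
        with pytest.raises(ValueError, match="g4"):
            res.predict(Xs)

    def test_identity_projection_returns_feature_values(self, separated_cohort):
        X, design = separated_cohort
        res = HealthManifold(X, design).fit()
        res.C = np.eye(5)[:, :1]
        v = res._raw_scores(X)[0]
        np.testing.assert_array_equal(v, X.values[:, 0])

    def test_serialisation_round_trip(self, separated_cohort):
        X, design = separated_cohort
        res = HealthManifold(X, design).fit()
        back = ManifoldResults.from_dict(res.to_dict())
        np.testing.assert_allclose(back.predict(X).v_neg_scaled,
                                   res.predict(X).v_neg_scaled, atol=1e-12)


class TestOrientationScaling:
    def test_target_scores_above_background(self, separated_cohort):
        X, design = separated_cohort
        vs = HealthManifold(X, design).fit().predict(X)
        assert vs.v_neg_scaled[8:].mean() > vs.v_neg_scaled[:8].mean()
        assert vs.v_neg_scaled.min() == pytest.approx(0.0)
        assert vs.v_neg_scaled.max() == pytest.approx(1.0)

    def test_global_sign_flip_leaves_scaled_scores_unchanged(self, separated_cohort):
        X, design = separated_cohort
        res = HealthManifold(X, design).fit()
        ref = res.predict(X).v_neg_scaled.copy()
        res.C = -res.C
        res._set_anchors(X, design)
        np.testing.assert_allclose(res.predict(X).v_neg_scaled, ref, atol=1e-12)

    def test_interpolated_sample_lands_inside_unit_interval(self, separated_cohort):
        X, design = separated_cohort
        res = HealthManifold(X, design).fit()
        mid = 0.5 * (X.values[:8].mean(axis=0) + X.values[8:].mean(axis=0))
        Xm = ExpressionMatrix(mid[None, :], ["mid"], X.feature_ids)
        v = res.predict(Xm).v_neg_scaled[0]
        assert 0.0 < v < 1.0

    def test_constant_matrix_rejected(self):
        X = make_matrix(np.ones((4, 3)))
        design = CohortDesign(X.sample_ids[:2], X.sample_ids[2:])
        with pytest.raises((DegenerateManifoldError, ValueError)):
            HealthManifold(X, design).fit()


class TestCVSelection:
    def test_noise_feature_less_stable_than_signal(self, rng):
        hits = 0
        for rep in range(10):
            r = np.random.default_rng(100 + rep)
            VH = r.standard_normal((12, 5))
            VD = r.standard_normal((12, 5))
            VD[:, 0] += 5.0
            ids = [f"h{i}" for i in range(12)] + [f"d{i}" for i in range(12)]
            X = ExpressionMatrix(np.vstack([VH, VD]), ids, [f"g{j}" for j in range(5)])
            design = CohortDesign(ids[:12], ids[12:])
            stab = cv_feature_selection(X, design, folds=10, seed=rep)
            hits += stab.cv[0] < stab.cv[1]  # signal vs a designated noise feature
        assert hits >= 9

    def test_retain_everything_keeps_all(self, separated_cohort):
        X, design = separated_cohort
        stab = cv_feature_selection(X, design, folds=4, retain_fraction=1.0)
        assert stab.kept.all()

    def test_retention_fraction_respected(self, rng):
        VH = rng.standard_normal((15, 10))
        VD = rng.standard_normal((15, 10)) + rng.normal(0, 2, 10)
        ids = [f"h{i}" for i in range(15)] + [f"d{i}" for i in range(15)]
        X = ExpressionMatrix(np.vstack([VH, VD]), ids, [f"g{j}" for j in range(10)])
        design = CohortDesign(ids[:15], ids[15:])
        stab = cv_feature_selection(X, design, folds=10, retain_fraction=0.7, seed=3)
        assert 0 < stab.kept.sum() <= 10
        kept_cv = stab.cv[stab.kept]
        dropped_cv = stab.cv[~stab.kept]
        if dropped_cv.size:
            assert kept_cv.max() <= dropped_cv.min()

    def test_too_few_folds_rejected(self, separated_cohort):
        X, design = separated_cohort
        with pytest.raises(ValueError):
            cv_feature_selection(X, design, folds=1)

    def test_small_groups_degrade_with_warning(self, separated_cohort):
        X, design = separated_cohort  # 8 per group < 10 folds
        with pytest.warns(UserWarning, match="folds"):
            stab = cv_feature_selection(X, design, folds=10)
        assert stab.coefficients.shape[0] == 8


class TestCombineAxes:
    @staticmethod
    def _vs(v, ids):
        from hsm.manifold import VScores

        v = np.asarray(v, float)
        return VScores(ids, -v, v, v, None)

    def test_identical_axes_reproduce_axis(self, rng):
        ids = [f"s{i}" for i in range(20)]
        v = rng.standard_normal(20)
        combined = combine_v_axes([self._vs(v, ids)] * 3)
        assert abs(np.corrcoef(combined, v)[0, 1]) == pytest.approx(1.0)
        assert np.corrcoef(combined, v)[0, 1] > 0  # target-high kept

    def test_anticorrelated_axes_keep_dominant_direction(self, rng):
        ids = [f"s{i}" for i in range(30)]
        v = rng.standard_normal(30)
        combined = combine_v_axes([self._vs(v, ids), self._vs(-0.99 * v, ids)])
        assert abs(np.corrcoef(combined, v)[0, 1]) > 0.99

    def test_matches_eigendecomposition_oracle(self, rng):
        ids = [f"s{i}" for i in range(25)]
        axes = [self._vs(rng.standard_normal(25), ids) for _ in range(3)]
        combined = combine_v_axes(axes)
        M = np.column_stack([a.v_neg for a in axes])
        Mc = M - M.mean(axis=0)
        _, vecs = np.linalg.eigh(np.cov(Mc, rowvar=False))
        oracle = Mc @ vecs[:, -1]
        assert abs(np.corrcoef(combined, oracle)[0, 1]) == pytest.approx(1.0)

    def test_mismatched_samples_rejected(self, rng):
        a = self._vs(rng.standard_normal(4), ["a", "b", "c", "d"])
        b = self._vs(rng.standard_normal(4), ["a", "b", "c", "e"])
        with pytest.raises(ValueError):
            combine_v_axes([a, b])


class TestTrajectoryRecovery:
    def test_stage_means_increase_on_synthetic_cohort(self):
        cfg = SimConfig(seed=7, drift=1.5)
        X = zscore_normalize(simulate_health_trajectory(cfg))
        res = HealthManifold(X, trajectory_design(X)).fit()
        f = res.predict(X).to_frame()
        means = f.groupby("stage")["v_neg_scaled"].mean()
        assert (means.diff().dropna() > 0).all()
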