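"""Encoding-model evaluation: design matrices, nested ridge CV, reconstruction."""

import numpy as np
import pandas as pd
import pytest

from modmatch.encoding import (
    LAMBDA_GRID,
    DesignMatrix,
    build_design_matrix,
    cross_predict,
    design_matrix_n_features,
    learn_reconstruction_weights,
    make_folds,
    regression_feature_table,
    ridge_fit_predict_nested_cv,
)
from modmatch.feature_stats import FeatureStatistics


def _design(n_sounds=36, n_features=18, seed=0, groups=None):
    rng = np.random.default_rng(seed)
    F = rng.standard_normal((n_sounds, n_features))
    groups = (np.array(["cochlear"] * (n_features // 2) + ["modulation"] *
                       (n_features - n_features // 2)) if groups is None else groups)
    return DesignMatrix(F, groups, pd.DataFrame(index=range(n_features)), "custom"), rng


class TestFeatureEnumeration:
    @pytest.mark.parametrize(
        "kind,count",
        [("spectrotemporal", 27_559), ("temporal", 2_170), ("spectral", 1_736),
         ("cochlear", 217)],
    )
    def test_printed_feature_counts(self, kind, count):
        assert design_matrix_n_features(kind) == count
        assert len(regression_feature_table(kind)) == count

    def test_lambda_grid_has_201_octave_steps(self):
        assert LAMBDA_GRID.size == 201
        assert LAMBDA_GRID[0] == 2.0**-100 and LAMBDA_GRID[-1] == 2.0**100
        np.testing.assert_allclose(LAMBDA_GRID[1:] / LAMBDA_GRID[:-1], 2.0)


class TestDesignMatrix:
    def _stats(self, rng, n_channels=6):
        labels, kinds = [], []
        for lbl, kind in [("cochleagram", "cochlear"), ("t=4Hz|s=all|none", "modulation"),
                          ("t=dc|s=all|none", "modulation"), ("t=4Hz|s=2cpo|up", "modulation")]:
            labels += [lbl] * n_channels
            kinds += [kind] * n_channels
        idx = pd.DataFrame({"feature_kind": kinds, "filter_label": labels,
                            "channel": list(range(n_channels)) * 4,
                            "frequency": list(range(n_channels)) * 4})
        return [
            FeatureStatistics(f"s{i}", "spectrotemporal",
                              rng.uniform(0.1, 1, len(idx)), idx)
            for i in range(8)
        ]

    def test_exclusions_applied(self):
        rng = np.random.default_rng(1)
        dm = build_design_matrix(self._stats(rng), "spectrotemporal")
        # temporal-DC and 1-D (t=...|s=all) modulation features are excluded
        assert dm.n_features == 12  # cochleagram block + oriented block
        assert set(dm.groups) == {"cochlear", "modulation"}

    def test_standardized_matrix_has_unit_column_structure(self):
        rng = np.random.default_rng(2)
        dm = build_design_matrix(self._stats(rng), "spectrotemporal")
        Z = dm.standardized()
        # last column is the bias
        np.testing.assert_allclose(Z[:, -1], 1.0)
        np.testing.assert_allclose(Z[:, :-1].mean(axis=0), 0.0, atol=1e-12)
        # group blocks have equal Frobenius norm after rescaling
        coch = Z[:, :-1][:, dm.groups == "cochlear"]
        mod = Z[:, :-1][:, dm.groups == "modulation"]
        assert np.linalg.norm(coch) == pytest.approx(np.linalg.norm(mod), rel=1e-9)


class TestFolds:
    def test_outer_folds_are_four_nines(self):
        folds = make_folds(36, 4, seed=0)
        assert [len(f) for f in folds] == [9, 9, 9, 9]
        assert sorted(np.concatenate(folds)) == list(range(36))

    def test_inner_folds_are_7776(self):
        folds = make_folds(27, 4, seed=0)
        assert sorted((len(f) for f in folds), reverse=True) == [7, 7, 7, 6]

    def test_bad_fold_count_rejected(self):
        with pytest.raises(ValueError):
            make_folds(5, 9)


class TestNestedRidgeCV:
    def test_planted_linear_voxels_recovered(self):
        """Noiseless responses generated as X z: corrected prediction NSE is
        ~0 and refit weights correlate > 0.99 with the planted weights."""
        dm, rng = _design(36, 15, seed=3)
        z = rng.standard_normal((15, 4))
        Z = dm.standardized()[:, :-1]
        Y = Z @ z
        result = ridge_fit_predict_nested_cv(dm, [Y, Y], seed=1, refit_full_weights=True)
        assert np.all(result.corrected_nse < 0.01)
        for v in range(4):
            r = np.corrcoef(result.weights[:, v], z[:, v])[0, 1]
            assert r > 0.99

    def test_fold_geometry_and_lambda_grid(self):
        dm, rng = _design(36, 10, seed=4)
        Y = rng.standard_normal((36, 2))
        result = ridge_fit_predict_nested_cv(dm, [Y, Y], seed=0)
        assert [len(f) for f in result.outer_folds] == [9, 9, 9, 9]
        assert sorted(result.inner_fold_sizes, reverse=True) == [7, 7, 7, 6]

    def test_ridge_path_matches_sklearn(self):
        """Independent oracle: sklearn Ridge at a few penalties reproduces the
        SVD filter-factor solution."""
        from sklearn.linear_model import Ridge

        from modmatch.encoding import _ridge_predictions

        rng = np.random.default_rng(5)
        Z = rng.standard_normal((30, 8))
        Z -= Z[:20].mean(axis=0)
        y = rng.standard_normal((30, 1))
        lambdas = [1e-3, 1.0, 1e3]
        ours = _ridge_predictions(Z, y[:20], np.arange(20), np.arange(20, 30), lambdas)
        for i, lam in enumerate(lambdas):
            sk = Ridge(alpha=lam, fit_intercept=True).fit(Z[:20], y[:20])
            np.testing.assert_allclose(ours[i][:, 0], sk.predict(Z[20:]).ravel(), atol=1e-8)

    def test_shuffled_responses_give_nse_near_one(self):
        """No-leakage permutation check: destroying the feature-response link
        leaves corrected prediction NSE ~1 on average."""
        dm, rng = _design(36, 12, seed=6)
        Z = dm.standardized()[:, :-1]
        z = rng.standard_normal((12, 30))
        Y = Z @ z + 0.01 * rng.standard_normal((36, 30))
        perm = rng.permutation(36)
        result = ridge_fit_predict_nested_cv(dm, [Y[perm], Y[perm][:, :]],
                                             train_response_reps=None, seed=2)
        # responses permuted relative to the design: no predictive signal
        dm_shuffled = DesignMatrix(dm.features[rng.permutation(36)], dm.groups,
                                   dm.feature_table, dm.model_kind)
        shuffled = ridge_fit_predict_nested_cv(dm_shuffled, [Y, Y], seed=2)
        assert np.mean(shuffled.corrected_nse) > 0.8

    def test_lambda_extremes(self):
        """As lambda -> inf predictions collapse to the training mean; as
        lambda -> 0 on a full-rank problem ridge approaches least squares."""
        from modmatch.encoding import _ridge_predictions

        rng = np.random.default_rng(7)
        Z = rng.standard_normal((20, 5))
        Z -= Z[:15].mean(axis=0)
        y = rng.standard_normal((15, 1))
        preds = _ridge_predictions(Z, y, np.arange(15), np.arange(15, 20),
                                   [2.0**-100, 2.0**100])
        w, *_ = np.linalg.lstsq(Z[:15], y - y.mean(), rcond=None)
        np.testing.assert_allclose(preds[0], Z[15:] @ w + y.mean(), atol=1e-8)
        np.testing.assert_allclose(preds[1], np.full((5, 1), y.mean()), atol=1e-6)


class TestCrossPredict:
    def test_identical_train_test_reduces_to_within_set(self):
        dm, rng = _design(36, 10, seed=8)
        Z = dm.standardized()[:, :-1]
        Y = Z @ rng.standard_normal((10, 3))
        within = ridge_fit_predict_nested_cv(dm, [Y, Y], seed=3)
        crossed = cross_predict(dm, [Y, Y], [Y, Y], seed=3)
        np.testing.assert_allclose(crossed.corrected_nse, within.corrected_nse, atol=1e-12)

    def test_shared_planted_model_cross_predicts_well(self):
        dm, rng = _design(36, 10, seed=9)
        Z = dm.standardized()[:, :-1]
        z = rng.standard_normal((10, 5))
        Y_nat = Z @ z + 0.02 * rng.standard_normal((36, 5))
        Y_match = Z @ z + 0.02 * rng.standard_normal((36, 5))
        crossed = cross_predict(dm, [Y_nat, Y_nat], [Y_match, Y_match], seed=4)
        assert np.median(crossed.corrected_nse) < 0.05

    def test_orthogonal_drive_surfaces_model_failure(self):
        """Voxels driven by a feature orthogonal to the design cross-predict
        poorly (high NSE), the signature of an inaccurate model."""
        dm, rng = _design(36, 10, seed=10)
        Z = dm.standardized()[:, :-1]
        hidden = rng.standard_normal((36, 1))
        hidden -= Z @ np.linalg.lstsq(Z, hidden, rcond=None)[0]  # orthogonalize
        Y_test = np.tile(hidden, (1, 4))
        Y_train = Z @ rng.standard_normal((10, 4))
        crossed = cross_predict(dm, [Y_train, Y_train], [Y_test, Y_test], seed=5)
        assert np.median(crossed.corrected_nse) > 0.5


class TestReconstructionWeights:
    def test_planted_components_recovered(self):
        rng = np.random.default_rng(11)
        n_sounds, n_voxels, k = 40, 60, 3
        comps = rng.standard_normal((n_sounds, k))
        mix = rng.standard_normal((k, n_voxels))
        voxels = comps @ mix + 0.01 * rng.standard_normal((n_sounds, n_voxels))
        cw = learn_reconstruction_weights(voxels, comps, seed=1)
        rec = cw.reconstruct(voxels)
        for j in range(k):
            assert np.corrcoef(rec[:, j], comps[:, j])[0, 1] > 0.99
        assert np.all(cw.cv_nse < 0.05)

    def test_single_voxel_identity_up_to_shrinkage(self):
        rng = np.random.default_rng(12)
        voxels = rng.standard_normal((30, 5))
        target = voxels[:, 2:3]
        cw = learn_reconstruction_weights(voxels, target, seed=2)
        rec = cw.reconstruct(voxels)
        assert np.corrcoef(rec[:, 0], target[:, 0])[0, 1] > 0.99

    def test_tsnr_threshold_excludes_voxels(self):
        rng = np.random.default_rng(13)
        voxels = rng.standard_normal((30, 6))
        target = voxels @ rng.standard_normal((6, 1))
        tsnr = np.array([50.0, 10.0, 50.0, 50.0, 20.0, 50.0])
        cw = learn_reconstruction_weights(voxels, target, seed=3, tsnr=tsnr)
        assert cw.voxel_mask.sum() == 4
        assert cw.weights.shape[0] == 4

    def test_rank_deficient_target_rejected(self):
        rng = np.random.default_rng(14)
        voxels = rng.standard_normal((20, 4))
        target = np.ones((20, 2))
        with pytest.raises(ValueError, match="rank"):
            learn_reconstruction_weights(voxels, target)
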