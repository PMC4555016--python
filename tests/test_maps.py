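"""Biomarker maps: Haufe patterns, back-projection, aggregation."""

import numpy as np
import pytest

from brainclass import (aggregate_maps, backproject, fdr_rank,
                        feature_weight_vector, fit_pca, flatten,
                        haufe_activation, project, run_nested_cv,
                        threshold_and_export, train)
from brainclass.crossval import ParamGrid
from brainclass.maps import DiscriminativeMap, compute_discriminative_map


@pytest.fixture()
def toy_classifier(rng):
    x = rng.normal(size=(12, 3)) + np.repeat([0, 1], 6)[:, None] * 2.0
    return train(x, np.repeat([0, 1], 6))


class TestFeatureWeightVector:
    def test_equals_primal_w(self, toy_classifier):
        np.testing.assert_allclose(feature_weight_vector(toy_classifier),
                                   toy_classifier.primal_w, atol=1e-10)

    def test_separable_direction_positive_in_1d(self):
        x = np.array([[-1.0], [1.0]])
        clf = train(x, np.array([-1, 1]), C=1e6)
        assert feature_weight_vector(clf)[0] > 0

    def test_orthogonal_displacement_leaves_decision_unchanged(self, rng):
        x = rng.normal(size=(10, 4)) + np.repeat([0, 1], 5)[:, None]
        clf = train(x, np.repeat([0, 1], 5))
        w = feature_weight_vector(clf)
        v = rng.normal(size=4)
        v -= (v @ w) / (w @ w) * w           # project out w
        q = rng.normal(size=4)
        from brainclass import decision_function
        d0 = decision_function(clf, q[None])[0]
        d1 = decision_function(clf, (q + 3.0 * v)[None])[0]
        assert d1 == pytest.approx(d0, abs=1e-8)

    def test_literal_unsigned_variant_differs(self, toy_classifier):
        unsigned = feature_weight_vector(toy_classifier, signed_by_label=False)
        assert not np.allclose(unsigned, toy_classifier.primal_w)


class TestHaufeActivation:
    def test_whitened_features_pattern_proportional_to_weight(self, rng):
        # isotropic features: covariance ~ identity
        x = rng.normal(size=(50000, 3))
        w = np.array([1.0, -2.0, 0.5])
        a = haufe_activation(w, x)
        np.testing.assert_allclose(a, w, atol=0.05)

    def test_diagonal_covariance_rescales_weight(self):
        # exact sample covariance diag(4, 1) via a fixed 4-point design
        x = np.array([[2.0, 1.0], [-2.0, -1.0], [2.0, -1.0], [-2.0, 1.0]])
        cov = np.cov(x.T, ddof=1)
        np.testing.assert_allclose(cov, np.diag([16 / 3, 4 / 3]))
        a = haufe_activation(np.array([1.0, 1.0]), x)
        np.testing.assert_allclose(a / a[1], [4.0, 1.0])

    def test_suppressor_feature_gets_zero_activation(self):
        """Classic two-feature suppressor: feature 2 carries only noise
        shared with feature 1; the classifier must weight it to cancel
        that noise, but its activation pattern entry is ~0."""
        rng = np.random.default_rng(7)
        n = 1500
        signal = np.repeat([-1.0, 1.0], n // 2)
        noise = rng.normal(size=n)
        x = np.column_stack([signal + noise, noise])
        labels = (signal > 0).astype(int)
        clf = train(x, labels, C=10.0, tol=1e-4)
        w = feature_weight_vector(clf)
        assert abs(w[1]) > 0.1 * abs(w[0])     # suppressor is genuinely used
        a = haufe_activation(w, x)
        # analytic oracle: Cov = [[2, 1], [1, 1]] for unit signal/noise
        oracle = np.array([[2.0, 1.0], [1.0, 1.0]]) @ w
        np.testing.assert_allclose(a, oracle, rtol=0.1, atol=0.05 * abs(a[0]))
        assert abs(a[1]) < 0.1 * abs(a[0])


class TestBackproject:
    @pytest.fixture()
    def fitted(self, small_phantom):
        fm = flatten(small_phantom, "GM")
        model = fit_pca(fm)
        coeff = project(model, fm)
        ranking = fdr_rank(coeff, small_phantom.labels)
        return fm, model, coeff, ranking

    def test_unit_pattern_recovers_loading_image(self, fitted):
        fm, model, _, ranking = fitted
        pattern = np.zeros(3)
        pattern[1] = 1.0
        out = backproject(pattern, model, ranking, 3)
        expected = fm.scatter(model.loadings[:, ranking.order[1]])
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_full_rank_roundtrip_recovers_centered_sample(self, fitted):
        fm, model, coeff, ranking = fitted
        pc = model.n_components
        pattern = coeff[4][ranking.order]
        out = backproject(pattern, model, ranking, pc)
        expected = fm.scatter(fm.values[4] - model.mean)
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_zero_pattern_zero_map(self, fitted):
        _, model, _, ranking = fitted
        out = backproject(np.zeros(2), model, ranking, 2)
        assert not out.any()

    def test_dimension_mismatch(self, fitted):
        _, model, _, ranking = fitted
        with pytest.raises(ValueError):
            backproject(np.zeros(3), model, ranking, 2)


class TestAggregate:
    def test_identical_maps_yield_their_normalization(self, rng):
        m = rng.normal(size=(5, 5, 5))
        out = aggregate_maps([m] * 20)
        expected = np.abs(m)
        expected = (expected - expected.min()) / np.ptp(expected)
        np.testing.assert_allclose(out.values, expected, atol=1e-12)
        assert out.n_folds_averaged == 20

    def test_normalization_contract(self, rng):
        out = aggregate_maps([rng.normal(size=(4, 4, 4)) for _ in range(3)])
        assert out.values.min() >= 0.0
        assert out.values.max() == pytest.approx(1.0)

    def test_degenerate_and_empty_inputs(self):
        with pytest.raises(ValueError, match="no maps"):
            aggregate_maps([])
        with pytest.raises(ValueError, match="constant"):
            aggregate_maps([np.ones((3, 3, 3))])

    def test_linear_in_dual_weights(self, small_phantom):
        """Doubling all dual weights doubles the unnormalized fold map."""
        from brainclass.maps import fold_map
        res = run_nested_cv(small_phantom, k=4,
                            grid=ParamGrid(tissues=("GM",), fwhms=(None,)),
                            seed=0)
        rec = res.folds[0]
        base = fold_map(rec)
        rec.classifier.dual_weights = rec.classifier.dual_weights * 2.0
        rec.classifier.primal_w = rec.classifier.primal_w * 2.0
        np.testing.assert_allclose(fold_map(rec), 2.0 * base, rtol=1e-10)


class TestThreshold:
    def _map(self, values):
        return DiscriminativeMap(values=np.asarray(values),
                                 n_folds_averaged=1)

    def test_zero_threshold_identity(self, rng):
        vals = rng.uniform(size=(3, 3, 3))
        vals.ravel()[0] = 1.0
        m = self._map(vals)
        np.testing.assert_array_equal(m.thresholded(0.0).values, vals)

    def test_unit_threshold_keeps_only_max(self):
        vals = np.array([[[0.2, 0.6], [1.0, 0.4]]])
        out = self._map(vals).thresholded(1.0).values
        np.testing.assert_array_equal(out, [[[0.0, 0.0], [1.0, 0.0]]])

    def test_half_threshold_example(self):
        vals = np.array([[[0.2, 0.6]]])
        out = self._map(vals).thresholded(0.5).values
        np.testing.assert_array_equal(out, [[[0.0, 0.6]]])

    def test_export_roundtrip(self, tmp_path, rng):
        import nibabel as nib
        vals = rng.uniform(size=(4, 4, 4))
        vals.ravel()[0] = 1.0
        path = threshold_and_export(self._map(vals), 0.5,
                                    tmp_path / "map.nii.gz")
        back = np.asarray(nib.load(str(path)).dataobj)
        np.testing.assert_allclose(
            back, np.where(vals >= 0.5, vals, 0).astype(np.float32))


def test_map_concentrates_on_true_roi(small_phantom, small_phantom_spec):
    """The averaged, normalized map is markedly higher inside the
    injected ROI than outside."""
    from brainclass import roi_mask
    res = run_nested_cv(small_phantom, k=4,
                        grid=ParamGrid(tissues=("GM",), fwhms=(None, 4.0)),
                        seed=0)
    dmap = compute_discriminative_map(res)
    mask = roi_mask(small_phantom_spec)
    assert dmap.values[mask].mean() > 2.0 * dmap.values[~mask].mean()
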