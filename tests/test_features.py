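"""PCA via the Gram matrix and FDR component ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainclass import (explained_variance_curve, fdr_rank, fit_pca, flatten,
                        project, variance_at_k)
from brainclass.features import reconstruct


@pytest.fixture(scope="module")
def noise_model():
    x = np.random.default_rng(42).normal(size=(12, 200))
    return x, fit_pca(x)


class TestFitPCA:
    def test_rank_bound_pc_equals_s_minus_1(self, noise_model):
        _, model = noise_model
        assert model.n_components == 11

    def test_duplicated_sample_gives_rank_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([0.0, 1.0, -1.0, 2.0])
        model = fit_pca(np.stack([a, a, b]))
        assert model.n_components == 1

    def test_degenerate_dataset_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_pca(np.ones((4, 50)))

    def test_loadings_orthonormal(self, noise_model):
        _, model = noise_model
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(model.n_components), atol=1e-8)

    def test_eigenvalues_descending_nonnegative(self, noise_model):
        _, model = noise_model
        ev = model.eigenvalues
        assert np.all(np.diff(ev) <= 0)
        assert np.all(ev >= 0)

    def test_full_rank_reconstruction(self, noise_model):
        x, model = noise_model
        coeff = project(model, x)
        rec = reconstruct(model, coeff)
        np.testing.assert_allclose(rec, x, rtol=1e-6, atol=1e-9)

    def test_matches_direct_covariance_eigendecomposition(self, rng):
        """Oracle: eigendecomposition of the explicit N x N covariance."""
        x = rng.normal(size=(10, 200))
        model = fit_pca(x)
        cov = np.cov(x.T, ddof=1)
        evals, evecs = np.linalg.eigh(cov)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        np.testing.assert_allclose(model.eigenvalues,
                                   evals[:model.n_components], rtol=1e-8)
        coeff = project(model, x)
        oracle = (x - x.mean(axis=0)) @ evecs[:, :model.n_components]
        for j in range(model.n_components):   # per-column sign freedom
            sign = np.sign(coeff[:, j] @ oracle[:, j])
            np.testing.assert_allclose(coeff[:, j], sign * oracle[:, j],
                                       atol=1e-6)


class TestProject:
    def test_training_coefficients_centered(self, noise_model):
        x, model = noise_model
        coeff = project(model, x)
        np.testing.assert_allclose(coeff.mean(axis=0), 0.0, atol=1e-8)

    def test_mean_image_projects_to_zero(self, noise_model):
        _, model = noise_model
        np.testing.assert_allclose(project(model, model.mean), 0.0, atol=1e-8)

    def test_dimension_mismatch(self, noise_model):
        _, model = noise_model
        with pytest.raises(ValueError, match="dimension"):
            project(model, np.zeros((3, 7)))


class TestFDR:
    def test_identical_class_means_score_zero(self):
        coeff = np.array([[1.0], [3.0], [1.0], [3.0]])
        labels = np.array([0, 0, 1, 1])
        assert fdr_rank(coeff, labels).scores[0] == 0.0

    def test_unit_score_case(self):
        # class means 1 and 0, unbiased class variances 0.5 each
        coeff = np.array([[1.5], [0.5], [0.5], [-0.5]])
        labels = np.array([0, 0, 1, 1])
        assert fdr_rank(coeff, labels).scores[0] == pytest.approx(1.0)

    def test_order_sorts_scores_descending(self, rng):
        labels = np.repeat([0, 1], 10)
        coeff = rng.normal(size=(20, 6))
        coeff[:, 2] += labels * 3.0          # make component 2 discriminative
        ranking = fdr_rank(coeff, labels)
        assert ranking.order[0] == 2
        assert np.all(np.diff(ranking.scores[ranking.order]) <= 0)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            fdr_rank(np.zeros((3, 2)), np.array([0, 1, 1]))

    @given(a=st.floats(min_value=0.1, max_value=50.0),
           c=st.floats(min_value=-100.0, max_value=100.0),
           flip=st.booleans())
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_invariant_to_affine_rescaling(self, a, c, flip):
        rng = np.random.default_rng(99)
        labels = np.repeat([0, 1], 8)
        coeff = rng.normal(size=(16, 4)) + labels[:, None] * rng.normal(size=4)
        scaled = coeff.copy()
        scaled[:, 1] = (-a if flip else a) * scaled[:, 1] + c
        np.testing.assert_allclose(fdr_rank(scaled, labels).scores,
                                   fdr_rank(coeff, labels).scores,
                                   rtol=1e-8)

    def test_top_component_tracks_group_label_on_phantom(self, small_phantom):
        fm = flatten(small_phantom, "GM")
        model = fit_pca(fm)
        coeff = project(model, fm)
        ranking = fdr_rank(coeff, small_phantom.labels)
        corr = np.array([abs(np.corrcoef(coeff[:, j], small_phantom.labels)[0, 1])
                         for j in range(model.n_components)])
        top = ranking.order[0]
        median = ranking.order[model.n_components // 2]
        assert corr[top] > corr[median]


class TestExplainedVariance:
    def _model(self, eigenvalues):
        pc = len(eigenvalues)
        return type("M", (), {"eigenvalues": np.asarray(eigenvalues, float),
                              "n_components": pc})()

    def test_equal_eigenvalues_linear_curve(self):
        curve = explained_variance_curve(self._model([2.0] * 4))
        np.testing.assert_allclose(curve, [0.25, 0.5, 0.75, 1.0])

    def test_curve_ends_at_one(self, noise_model):
        x, model = noise_model
        ranking = fdr_rank(project(model, x), np.repeat([0, 1], 6))
        for r in (None, ranking):
            curve = explained_variance_curve(model, r)
            assert np.all(np.diff(curve) >= -1e-15)
            assert curve[-1] == pytest.approx(1.0, abs=1e-12)

    def test_variance_at_k_respects_ranking(self):
        model = self._model([3.0, 1.0])
        identity = type("R", (), {"order": np.array([0, 1])})()
        swapped = type("R", (), {"order": np.array([1, 0])})()
        assert variance_at_k(model, identity, 1) == pytest.approx(0.75)
        assert variance_at_k(model, swapped, 1) == pytest.approx(0.25)
        assert variance_at_k(model, identity, 2) == pytest.approx(1.0)

    def test_k_out_of_range(self):
        model = self._model([1.0, 1.0])
        with pytest.raises(ValueError):
            variance_at_k(model, None, 3)
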