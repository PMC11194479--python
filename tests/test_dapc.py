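"""DAPC engine: imputation, fitting, posteriors, and equivalence with an
independent linear-discriminant oracle at full principal-axis retention."""

import numpy as np
import pytest
import scipy.linalg

from aimpanel import (
    AlleleCountMatrix,
    DapcModel,
    DegenerateFitError,
    default_n_pca,
    fit_dapc,
    impute_missing,
    predict_assignments,
    to_allele_counts,
)
from .conftest import make_diagnostic_gset


def acm(values, mask=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.zeros(values.shape, dtype=bool)
    return AlleleCountMatrix(
        values=values,
        column_names=[f"c{j}" for j in range(values.shape[1])],
        missing_mask=np.asarray(mask, dtype=bool),
        column_to_locus=np.arange(values.shape[1]),
    )


def brute_force_lda(X_train, labels, X_test):
    """Independent oracle: Fisher discriminant computed directly on the raw
    columns, posteriors from Mahalanobis distances under the pooled
    within-group covariance with equal priors."""
    X_train = np.asarray(X_train, float)
    labels = np.asarray(labels)
    groups = sorted(set(labels.tolist()))
    mu = {g: X_train[labels == g].mean(axis=0) for g in groups}
    n, p = X_train.shape
    W = sum(
        (X_train[labels == g] - mu[g]).T @ (X_train[labels == g] - mu[g])
        for g in groups
    )
    Sw = W / (n - len(groups))
    Sw_inv = np.linalg.pinv(Sw)
    d2 = np.stack(
        [
            np.einsum("ij,jk,ik->i", X_test - mu[g], Sw_inv, X_test - mu[g])
            for g in groups
        ],
        axis=1,
    )
    logk = -0.5 * d2
    logk -= logk.max(axis=1, keepdims=True)
    post = np.exp(logk)
    post /= post.sum(axis=1, keepdims=True)
    return [groups[i] for i in np.argmax(post, axis=1)], post


def random_fixture(rng, n_groups=None, n_cols=None):
    n_groups = n_groups or int(rng.integers(2, 4))
    n_cols = n_cols or int(rng.integers(2, 5))
    n = int(rng.integers(n_groups * 5, 31))
    y = np.array([f"g{i % n_groups}" for i in range(n)])
    means = rng.normal(0.0, 2.0, size=(n_groups, n_cols))
    X = np.vstack(
        [rng.normal(means[int(l[1:])], 1.0, size=n_cols) for l in y]
    )
    return X, y


class TestImputeMissing:
    def test_missing_becomes_column_mean(self):
        a = acm([[0.0], [2.0], [0.0]], mask=[[False], [False], [True]])
        out = impute_missing(a)
        assert out.values[2, 0] == pytest.approx(1.0)
        assert not out.missing_mask.any()

    def test_no_missing_is_identity(self):
        a = acm([[0.0, 2.0], [1.0, 1.0]])
        out = impute_missing(a)
        assert np.array_equal(out.values, a.values)

    def test_test_matrix_uses_training_means(self):
        # Training mean is 2.0; the test matrix's own mean would be 0.0.
        test = acm([[0.0], [0.0], [5.0]], mask=[[False], [False], [True]])
        out = impute_missing(test, column_means=np.array([2.0]))
        assert out.values[2, 0] == pytest.approx(2.0)

    def test_all_missing_column_raises(self):
        a = acm([[1.0], [1.0]], mask=[[True], [True]])
        with pytest.raises(ValueError, match="no non-missing"):
            impute_missing(a)


class TestFitDapc:
    def test_perfect_separation_posteriors(self, diagnostic_gset):
        counts = to_allele_counts(diagnostic_gset)
        model = fit_dapc(counts, diagnostic_gset.pop_labels)
        out = predict_assignments(model, counts)
        assert out.assigned_label == diagnostic_gset.pop_labels
        assert np.all(out.max_posterior > 0.99)
        assert model.n_da == 1  # two groups

    def test_null_labels_give_near_zero_discrimination(self, rng):
        X = rng.normal(size=(60, 4))
        y = rng.permutation(["a"] * 30 + ["b"] * 30)
        model = fit_dapc(X, y, n_pca=4)
        gap = np.linalg.norm(model.group_centroids[0] - model.group_centroids[1])
        sep = fit_dapc(X + np.where(np.array(y) == "a", 0, 50)[:, None], y, n_pca=4)
        sep_gap = np.linalg.norm(sep.group_centroids[0] - sep.group_centroids[1])
        assert gap < 0.05 * sep_gap

    def test_small_group_raises(self):
        X = np.arange(8.0).reshape(4, 2)
        with pytest.raises(DegenerateFitError, match="need >= 2"):
            fit_dapc(X, ["a", "a", "a", "b"])

    def test_identical_rows_raise(self):
        X = np.ones((6, 3))
        with pytest.raises(DegenerateFitError, match="variance"):
            fit_dapc(X, ["a"] * 3 + ["b"] * 3)

    def test_default_retention_rule(self):
        assert default_n_pca(30, 50) == 10   # floor(n/3)
        assert default_n_pca(30, 4) == 4     # capped by columns
        assert default_n_pca(4, 50) == 1     # floor(4/3)
        assert default_n_pca(2, 50) == 1     # never below 1

    def test_single_column_panel_is_legal(self):
        X = np.array([[0.0], [0.0], [1.0], [2.0], [2.0], [2.0]])
        model = fit_dapc(X, ["a", "a", "a", "b", "b", "b"], n_pca=5)
        assert model.n_pca == 1 and model.n_da == 1


class TestPredict:
    def test_midpoint_gets_half_posterior(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [4.0, 0.0], [4.0, 1.0]])
        y = ["a", "a", "b", "b"]
        model = fit_dapc(X, y, n_pca=2)
        out = predict_assignments(model, np.array([[2.0, 0.5]]))
        assert out.posterior[0] == pytest.approx([0.5, 0.5], abs=1e-9)
        assert out.assigned_label == ["a"]  # tie broken by label order

    def test_column_mismatch_raises(self, diagnostic_gset):
        counts = to_allele_counts(diagnostic_gset)
        model = fit_dapc(counts, diagnostic_gset.pop_labels)
        bad = acm(np.zeros((2, 3)))
        with pytest.raises(ValueError, match="columns"):
            predict_assignments(model, bad)

    def test_posterior_rows_sum_to_one(self, rng):
        X, y = random_fixture(rng)
        model = fit_dapc(X, y, n_pca=X.shape[1])
        out = predict_assignments(model, X)
        assert np.allclose(out.posterior.sum(axis=1), 1.0, atol=1e-9)

    def test_oracle_equivalence_full_retention(self, rng):
        """At full PC retention the DAPC must reproduce a plain linear
        discriminant analysis computed directly on the count matrix."""
        for _ in range(100):
            X, y = random_fixture(rng)
            model = fit_dapc(X, y, n_pca=X.shape[1])
            out = predict_assignments(model, X)
            exp_labels, exp_post = brute_force_lda(X, y, X)
            assert out.assigned_label == exp_labels
            assert np.allclose(out.posterior, exp_post, atol=1e-6)


class TestInvariances:
    def test_column_permutation_equivariance(self, rng):
        X, y = random_fixture(rng, n_groups=2, n_cols=4)
        perm = rng.permutation(4)
        m1 = fit_dapc(X, y, n_pca=4)
        m2 = fit_dapc(X[:, perm], y, n_pca=4)
        p1 = predict_assignments(m1, X).posterior
        p2 = predict_assignments(m2, X[:, perm]).posterior
        assert np.allclose(p1, p2, atol=1e-8)

    def test_column_shift_invariance(self, rng):
        X, y = random_fixture(rng, n_groups=2, n_cols=3)
        m1 = fit_dapc(X, y, n_pca=3)
        m2 = fit_dapc(X + np.array([5.0, -3.0, 100.0]), y, n_pca=3)
        p1 = predict_assignments(m1, X).posterior
        p2 = predict_assignments(m2, X + np.array([5.0, -3.0, 100.0])).posterior
        assert np.allclose(p1, p2, atol=1e-8)

    def test_mean_confidence_monotone_in_separation(self):
        rng = np.random.default_rng(7)
        n = 40
        y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        noise = rng.normal(size=(n, 3))
        confidences = []
        for delta in (0.0, 0.5, 1.0, 2.0, 4.0):
            X = noise + np.where(y == "a", 0.0, delta)[:, None]
            model = fit_dapc(X, y, n_pca=3)
            confidences.append(predict_assignments(model, X).max_posterior.mean())
        assert all(b >= a - 1e-12 for a, b in zip(confidences, confidences[1:]))


class TestSerialization:
    def test_json_roundtrip(self, tmp_path, rng):
        X, y = random_fixture(rng)
        model = fit_dapc(X, y)
        path = tmp_path / "model.json"
        model.save(path)
        back = DapcModel.load(path)
        p1 = predict_assignments(model, X).posterior
        p2 = predict_assignments(back, X).posterior
        assert np.allclose(p1, p2, atol=1e-12)
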