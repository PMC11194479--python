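"""Discriminant analysis of principal components (DAPC) for population
assignment.

The classifier follows the standard two-stage construction: allele-count
columns are centred (optionally unit-scaled), projected onto the top
principal axes, and a linear discriminant analysis is fitted in the retained
PC space.  New individuals are projected through the same transformation and
assigned by Mahalanobis-type distance to the group centroids under the
pooled within-group covariance, with equal group priors; normalizing the
resulting Gaussian kernels over groups yields posterior membership
probabilities.

Design notes
------------
* The default principal-axis retention rule is
  ``min(floor(n_train / 3), n_columns, n_train - 1)`` — the usual
  over-fitting guard for DAPC-style workflows; it can be overridden with an
  explicit count.
* Allele counts share a scale, so the default is centring only; pass
  ``scale=True`` for unit-variance scaling.
* Argmax ties are broken by group-label sort order, deterministically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .genotypes import AlleleCountMatrix

__all__ = [
    "DapcModel",
    "AssignmentOutcome",
    "DegenerateFitError",
    "impute_missing",
    "default_n_pca",
    "fit_dapc",
    "predict_assignments",
]

_EIG_TOL = 1e-9
_RIDGE = 1e-8


class DegenerateFitError(ValueError):
    """Raised when a DAPC fit is impossible: a group with fewer than two
    training members, or zero total variance (all rows identical)."""


@dataclass
class DapcModel:
    """A fitted DAPC transformation, sufficient to assign new individuals."""

    column_names: list[str]
    center: np.ndarray               # (n_columns,)
    scale: np.ndarray                # (n_columns,), ones when unscaled
    pc_loadings: np.ndarray          # (n_columns, n_pca)
    da_coefficients: np.ndarray      # (n_pca, n_da)
    group_labels: list[str]          # sorted
    group_centroids: np.ndarray      # (n_groups, n_da)
    pooled_within_covariance: np.ndarray  # (n_da, n_da)

    @property
    def n_pca(self) -> int:
        return self.pc_loadings.shape[1]

    @property
    def n_da(self) -> int:
        return self.da_coefficients.shape[1]

    def transform(self, values: np.ndarray) -> np.ndarray:
        """Project raw count rows into the discriminant space."""
        X = (np.asarray(values, dtype=float) - self.center) / self.scale
        return X @ self.pc_loadings @ self.da_coefficients

    def to_dict(self) -> dict:
        return {
            "column_names": self.column_names,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "pc_loadings": self.pc_loadings.tolist(),
            "da_coefficients": self.da_coefficients.tolist(),
            "group_labels": self.group_labels,
            "group_centroids": self.group_centroids.tolist(),
            "pooled_within_covariance": self.pooled_within_covariance.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DapcModel":
        return cls(
            column_names=list(d["column_names"]),
            center=np.asarray(d["center"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            pc_loadings=np.asarray(d["pc_loadings"], dtype=float),
            da_coefficients=np.asarray(d["da_coefficients"], dtype=float),
            group_labels=list(d["group_labels"]),
            group_centroids=np.asarray(d["group_centroids"], dtype=float),
            pooled_within_covariance=np.asarray(
                d["pooled_within_covariance"], dtype=float
            ),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "DapcModel":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class AssignmentOutcome:
    """Posterior membership probabilities and argmax assignments."""

    posterior: np.ndarray        # (n_test, n_groups), rows on the simplex
    group_labels: list[str]
    assigned_label: list[str]
    max_posterior: np.ndarray    # (n_test,)


def impute_missing(
    counts: AlleleCountMatrix, column_means: np.ndarray | None = None
) -> AlleleCountMatrix:
    """Replace masked entries by column means and clear the mask.

    When ``column_means`` is None the means are computed from this matrix's
    own non-missing entries (training case); for a test matrix, pass the
    training-column means so train and test share the imputation reference.
    """
    values = counts.values.astype(float).copy()
    mask = counts.missing_mask
    if column_means is None:
        present = ~mask
        n_present = present.sum(axis=0)
        if np.any(n_present == 0):
            bad = counts.column_names[int(np.argmin(n_present))]
            raise ValueError(
                f"column {bad!r} has no non-missing entries and no supplied mean"
            )
        sums = np.where(mask, 0.0, values).sum(axis=0)
        column_means = sums / n_present
    else:
        column_means = np.asarray(column_means, dtype=float)
        if column_means.shape != (counts.n_columns,):
            raise ValueError("column_means length does not match column count")
    rows, cols = np.nonzero(mask)
    values[rows, cols] = column_means[cols]
    return AlleleCountMatrix(
        values=values,
        column_names=counts.column_names,
        missing_mask=np.zeros_like(mask),
        column_to_locus=counts.column_to_locus,
    )


def default_n_pca(n_train: int, n_columns: int) -> int:
    """Default principal-axis retention: min(floor(n/3), columns, n-1), >= 1."""
    return max(1, min(n_train // 3, n_columns, n_train - 1))


def fit_dapc(
    train_counts: AlleleCountMatrix | np.ndarray,
    labels,
    n_pca: int | None = None,
    n_da: int | None = None,
    scale: bool = False,
    column_names: list[str] | None = None,
) -> DapcModel:
    """Fit the DAPC classifier on a complete (no missing) count matrix.

    Parameters
    ----------
    train_counts
        Complete AlleleCountMatrix, or a plain 2-D array together with
        ``column_names``.
    labels
        Population label per training row; every group needs >= 2 members
        and >= 2 groups must be present.
    n_pca
        Retained principal axes; None applies :func:`default_n_pca`.  The
        count is further capped at the numerical rank of the centred data.
    n_da
        Discriminant axes; None retains ``n_groups - 1`` (capped at n_pca).
    scale
        Unit-variance scaling of columns in addition to centring.
    """
    if isinstance(train_counts, AlleleCountMatrix):
        if train_counts.missing_mask.any():
            raise ValueError("training matrix contains missing entries; impute first")
        X = train_counts.values.astype(float)
        column_names = list(train_counts.column_names)
    else:
        X = np.asarray(train_counts, dtype=float)
        if column_names is None:
            column_names = [f"col_{j}" for j in range(X.shape[1])]
    labels = [str(l) for l in labels]
    n, p = X.shape
    if len(labels) != n:
        raise ValueError("labels length does not match row count")

    group_labels = sorted(set(labels))
    if len(group_labels) < 2:
        raise DegenerateFitError("at least 2 groups are required")
    y = np.array([group_labels.index(l) for l in labels])
    counts_per_group = np.bincount(y, minlength=len(group_labels))
    for g, c in zip(group_labels, counts_per_group):
        if c < 2:
            raise DegenerateFitError(f"group {g!r} has {c} training member(s); need >= 2")

    center = X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
    else:
        sd = np.ones(p)
    Xc = (X - center) / sd

    # Principal axes: right singular vectors of the centred data.
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(S > _EIG_TOL * max(S[0], 1.0))) if S.size else 0
    if rank == 0:
        raise DegenerateFitError("zero total variance: all training rows identical")
    if n_pca is None:
        n_pca = default_n_pca(n, p)
    n_pca = max(1, min(int(n_pca), rank))
    loadings = Vt[:n_pca].T                      # (p, n_pca)
    scores = Xc @ loadings                       # (n, n_pca)

    n_groups = len(group_labels)
    max_da = min(n_groups - 1, n_pca)
    n_da = max_da if n_da is None else max(1, min(int(n_da), max_da))

    # Between- and within-group scatter in PC space.
    grand = scores.mean(axis=0)
    B = np.zeros((n_pca, n_pca))
    W = np.zeros((n_pca, n_pca))
    centroids_pc = np.empty((n_groups, n_pca))
    for k in range(n_groups):
        Zk = scores[y == k]
        mk = Zk.mean(axis=0)
        centroids_pc[k] = mk
        B += len(Zk) * np.outer(mk - grand, mk - grand)
        Wk = Zk - mk
        W += Wk.T @ Wk
    # Ridge keeps the generalized eigenproblem well-posed at tiny panel sizes.
    W_reg = W + _RIDGE * (np.trace(W) / n_pca + 1.0) * np.eye(n_pca)
    eigvals, eigvecs = scipy.linalg.eigh(B, W_reg)
    order = np.argsort(eigvals)[::-1][:n_da]
    da_coefficients = eigvecs[:, order]          # (n_pca, n_da)

    Z = scores @ da_coefficients
    group_centroids = centroids_pc @ da_coefficients
    pooled = np.zeros((n_da, n_da))
    for k in range(n_groups):
        D = Z[y == k] - group_centroids[k]
        pooled += D.T @ D
    pooled /= max(n - n_groups, 1)
    if np.linalg.matrix_rank(pooled) < n_da or np.linalg.cond(pooled) > 1e12:
        pooled = pooled + _RIDGE * np.eye(n_da)

    return DapcModel(
        column_names=column_names,
        center=center,
        scale=sd,
        pc_loadings=loadings,
        da_coefficients=da_coefficients,
        group_labels=group_labels,
        group_centroids=group_centroids,
        pooled_within_covariance=pooled,
    )


def predict_assignments(
    model: DapcModel, test_counts: AlleleCountMatrix | np.ndarray
) -> AssignmentOutcome:
    """Assign test individuals to groups with posterior membership
    probabilities.

    Rows are centred/scaled with the model's training parameters, projected
    through the principal and discriminant axes, and scored by squared
    Mahalanobis distance to each group centroid under the pooled
    within-group covariance; posteriors normalize the Gaussian kernels
    ``exp(-d^2/2)`` over groups with equal priors.
    """
    if isinstance(test_counts, AlleleCountMatrix):
        if test_counts.missing_mask.any():
            raise ValueError("test matrix contains missing entries; impute first")
        if list(test_counts.column_names) != list(model.column_names):
            raise ValueError("test columns do not match the model's training columns")
        X = test_counts.values
    else:
        X = np.asarray(test_counts, dtype=float)
        if X.shape[1] != len(model.column_names):
            raise ValueError("test columns do not match the model's training columns")
    Z = model.transform(X)                                   # (m, n_da)
    inv = np.linalg.inv(model.pooled_within_covariance)
    diffs = Z[:, None, :] - model.group_centroids[None, :, :]  # (m, g, d)
    d2 = np.einsum("mgd,de,mge->mg", diffs, inv, diffs)
    log_kernel = -0.5 * d2
    log_kernel -= log_kernel.max(axis=1, keepdims=True)
    post = np.exp(log_kernel)
    post /= post.sum(axis=1, keepdims=True)
    # argmax returns the first maximum; labels are sorted, so ties break by
    # group-label order.
    idx = np.argmax(post, axis=1)
    return AssignmentOutcome(
        posterior=post,
        group_labels=list(model.group_labels),
        assigned_label=[model.group_labels[i] for i in idx],
        max_posterior=post[np.arange(post.shape[0]), idx],
    )
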