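"""Global variance structure: PCA on the most variable sites and per-site
sequential (Type-I) ANOVA variance decomposition."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "PcaResult",
    "top_variable_sites",
    "MethylationPCA",
    "pca",
    "variance_components",
    "encode_covariates",
]


@dataclass
class PcaResult:
    scores: np.ndarray  # samples x k
    variance_explained: np.ndarray  # fractions, non-increasing
    components: np.ndarray  # k x sites loadings
    site_index: np.ndarray | None = None


def top_variable_sites(m, n_top: int) -> np.ndarray:
    """Indices of the n_top sites by descending across-sample variance of
    smoothed values; ties broken by genomic order (lower index first)."""
    values = m.smoothed if hasattr(m, "smoothed") and m.smoothed is not None else np.asarray(m)
    var = values.var(axis=1, ddof=1)
    n_sites = var.size
    if n_top > n_sites:
        warnings.warn("n_top exceeds site count; returning all sites", stacklevel=2)
        n_top = n_sites
    # stable sort on -variance keeps genomic order among ties
    order = np.argsort(-var, kind="stable")
    return order[:n_top]


class MethylationPCA(BaseEstimator, TransformerMixin):
    """Covariance PCA (centering only, no scaling) via SVD.

    Input to ``fit``/``transform`` is samples x sites. Components are the
    right singular vectors of the column-centered matrix; each component's
    sign is fixed by making its largest-magnitude loading positive.
    Fitted attributes: ``components_`` (k x sites), ``explained_variance_ratio_``,
    ``scores_`` (samples x k).
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("PCA needs at least 2 samples")
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        total = (s**2).sum()
        k = self.n_components or min(X.shape)
        k = min(k, s.size)
        # sign convention: largest-|loading| entry of each component positive
        for i in range(k):
            j = np.argmax(np.abs(Vt[i]))
            if Vt[i, j] < 0:
                Vt[i] = -Vt[i]
                U[:, i] = -U[:, i]
        self.components_ = Vt[:k]
        self.singular_values_ = s[:k]
        if total > 0:
            self.explained_variance_ratio_ = s[:k] ** 2 / total
        else:  # constant matrix: defined behavior, zero variance explained
            self.explained_variance_ratio_ = np.zeros(k)
        self.scores_ = U[:, :k] * s[:k]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_.T


def pca(values: np.ndarray, n_components: int | None = None, site_index=None) -> PcaResult:
    """PCA of a sites x samples matrix (centered per site across samples)."""
    est = MethylationPCA(n_components=n_components).fit(np.asarray(values).T)
    return PcaResult(
        scores=est.scores_,
        variance_explained=est.explained_variance_ratio_,
        components=est.components_,
        site_index=None if site_index is None else np.asarray(site_index),
    )


def encode_covariates(covariates: pd.DataFrame, order: list[str] | None = None):
    """One-hot encode categoricals (reference level dropped) in a stated order.

    Returns (design columns without intercept, list of (term, column slice)).
    """
    if order is None:
        order = list(covariates.columns)
    blocks, names = [], []
    col = 0
    for term in order:
        x = covariates[term]
        if x.dtype.kind in "OUSb" or isinstance(x.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(x, drop_first=True).to_numpy(dtype=float)
        else:
            dummies = x.to_numpy(dtype=float)[:, None]
        blocks.append(dummies)
        names.append((term, slice(col, col + dummies.shape[1])))
        col += dummies.shape[1]
    return np.column_stack(blocks), names


def variance_components(
    site_values: np.ndarray,
    covariates: pd.DataFrame,
    order: list[str] | None = None,
    tol: float = 1e-10,
) -> pd.DataFrame:
    """Sequential (Type-I) ANOVA variance fractions per site.

    ``site_values`` is sites x samples (a single site may be passed as a
    1-D vector). Each term's sequential sum of squares, in the stated
    order, is divided by the total sum of squares about the mean; the
    residual completes each row to 1. Collinear design columns are dropped
    with a warning and recorded in the ``dropped`` attribute of the result.
    """
    Y = np.atleast_2d(np.asarray(site_values, dtype=float))
    n = Y.shape[1]
    if len(covariates) != n:
        raise ValueError("covariate rows must match samples")
    if order is None:
        order = list(covariates.columns)
    X, blocks = encode_covariates(covariates, order)
    # orthogonalize columns in order against the intercept and predecessors
    cols = [np.ones(n) / np.sqrt(n)]
    keep = []
    dropped = []
    for j in range(X.shape[1]):
        v = X[:, j].astype(float)
        for q in cols:
            v = v - q * (q @ v)
        nv = np.linalg.norm(v)
        if nv < tol * max(1.0, np.linalg.norm(X[:, j])):
            dropped.append(j)
            keep.append(None)
            continue
        q = v / nv
        cols.append(q)
        keep.append(q)
    if dropped:
        warnings.warn(f"dropped {len(dropped)} collinear design column(s)", stacklevel=2)

    Yc = Y - Y.mean(axis=1, keepdims=True)
    tss = (Yc**2).sum(axis=1)
    tss_safe = np.where(tss > 0, tss, 1.0)
    out = {}
    for term, sl in blocks:
        ss = np.zeros(Y.shape[0])
        for j in range(sl.start, sl.stop):
            q = keep[j]
            if q is None:
                continue
            proj = Yc @ q
            ss += proj**2
        out[term] = ss / tss_safe
    df = pd.DataFrame(out)
    df["residual"] = 1.0 - df.sum(axis=1)
    df.loc[tss == 0, :] = 0.0
    df.loc[tss == 0, "residual"] = 1.0
    df.attrs["order"] = list(order)
    df.attrs["dropped_columns"] = dropped
    return df
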