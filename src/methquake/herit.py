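"""Per-site cis-heritability and stratified LD-score heritability enrichment.

A GRM is built from standardized dosages of SNPs around each CpG; samples
are pruned so that no pair exceeds a relatedness threshold; heritability is
estimated by restricted maximum likelihood with a single genetic variance
component, profiled exactly in one dimension after rotating into the GRM
eigenbasis. Annotation enrichment of GWAS heritability is estimated by
regressing chi-square statistics on annotation-partitioned LD scores with
block-jackknife standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "GrmMatrix",
    "H2Estimate",
    "PartitionedH2Result",
    "compute_grm",
    "prune_related",
    "reml_h2",
    "RemlHeritability",
    "ld_scores",
    "StratifiedLdRegression",
    "stratified_regression",
]


@dataclass
class GrmMatrix:
    values: np.ndarray  # samples x samples, symmetric
    sample_ids: list[str]
    n_snps: int


@dataclass
class H2Estimate:
    h2: float
    se: float
    lrt_p: float
    boundary: bool
    non_identifiable: bool
    loglik: float
    sigma2_g: float
    sigma2_e: float


@dataclass
class PartitionedH2Result:
    annotations: list[str]
    tau: np.ndarray
    tau_se: np.ndarray
    h2_share: np.ndarray
    snp_proportion: np.ndarray
    enrichment: np.ndarray
    enrichment_se: np.ndarray
    enrichment_p: np.ndarray
    intercept: float
    h2_total: float


# ---------------------------------------------------------------------------
# GRM


def compute_grm(dosages: np.ndarray, sample_ids: list[str] | None = None) -> GrmMatrix:
    """GRM A = Z Z' / m from standardized dosages (samples x SNPs).

    Each SNP is centered at 2p and scaled by sqrt(2p(1-p)); monomorphic
    SNPs are skipped with a count. All SNPs monomorphic is an error.
    """
    X = np.asarray(dosages, dtype=float)
    n, m = X.shape
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1) & (X.std(axis=0) > 0)
    if not poly.any():
        raise ValueError("all SNPs are monomorphic or constant")
    Xp = X[:, poly]
    pp = p[poly]
    Z = (Xp - 2 * pp) / np.sqrt(2 * pp * (1 - pp))
    A = Z @ Z.T / Z.shape[1]
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(n)]
    return GrmMatrix(values=A, sample_ids=list(sample_ids), n_snps=int(poly.sum()))


def prune_related(grm: GrmMatrix, threshold: float = 0.025) -> np.ndarray:
    """Greedy pruning until all off-diagonal relatedness < threshold.

    Repeatedly drops the member of an offending pair with the most
    offending partners (ties broken by sample id order). Returns indices of
    retained samples.
    """
    A = grm.values
    n = A.shape[0]
    active = np.ones(n, dtype=bool)
    off = np.abs(A) >= threshold
    np.fill_diagonal(off, False)
    while True:
        counts = (off & active[None, :] & active[:, None]).sum(axis=1)
        counts[~active] = 0
        worst = counts.max()
        if worst == 0:
            break
        candidates = np.flatnonzero(counts == worst)
        active[candidates[0]] = False
    return np.flatnonzero(active)


# ---------------------------------------------------------------------------
# single-component REML


def _restricted_loglik(h2: float, lam: np.ndarray, y2: np.ndarray) -> float:
    """Profile restricted log-likelihood at heritability h2.

    ``lam`` are eigenvalues of the covariate-projected GRM and ``y2`` the
    squared rotated responses; the total variance is profiled out
    analytically.
    """
    w = h2 * lam + (1.0 - h2)
    if np.any(w <= 0):
        return -np.inf
    k = y2.size
    sigma2 = float((y2 / w).sum() / k)
    if sigma2 <= 0:
        return -np.inf
    return -0.5 * (k * np.log(sigma2) + np.log(w).sum() + k)


def reml_h2(y: np.ndarray, grm: GrmMatrix, covariates: np.ndarray | None = None) -> H2Estimate:
    """REML heritability h2 = sigma2_g / (sigma2_g + sigma2_e) on [0, 1].

    Covariates (plus an intercept) are projected out, the projected GRM is
    rotated into its eigenbasis, and the restricted likelihood is profiled
    over h2 by bounded 1-D optimization. The likelihood-ratio test against
    h2 = 0 uses the boundary 0.5 chi2_0 + 0.5 chi2_1 mixture.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    C = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, dtype=float).reshape(n, -1)]
    )
    Qc, _ = np.linalg.qr(C)
    # orthogonal complement basis of the covariate span
    full, _ = np.linalg.qr(np.column_stack([Qc, np.eye(n)]))
    Q2 = full[:, C.shape[1] : n]
    Ky = Q2.T @ grm.values @ Q2
    lam, U = np.linalg.eigh((Ky + Ky.T) / 2.0)
    yr = U.T @ (Q2.T @ y)
    y2 = yr**2

    non_identifiable = float(np.ptp(lam)) < 1e-8
    res = optimize.minimize_scalar(
        lambda h: -_restricted_loglik(h, lam, y2),
        bounds=(0.0, 1.0),
        method="bounded",
        options={"xatol": 1e-8},
    )
    h2 = float(res.x)
    ll_opt = -float(res.fun)
    ll0 = _restricted_loglik(0.0, lam, y2)
    if ll0 > ll_opt:  # optimizer missed the boundary
        h2, ll_opt = 0.0, ll0
    lrt = max(0.0, 2.0 * (ll_opt - ll0))
    lrt_p = 0.5 * float(stats.chi2.sf(lrt, df=1)) if lrt > 0 else 1.0
    boundary = h2 < 1e-6 or h2 > 1 - 1e-6

    # curvature-based standard error; guarded at the boundary
    eps = 1e-4
    h_lo, h_hi = max(h2 - eps, 0.0), min(h2 + eps, 1.0)
    f0 = _restricted_loglik(h2, lam, y2)
    f1 = _restricted_loglik(h_lo, lam, y2)
    f2 = _restricted_loglik(h_hi, lam, y2)
    d2 = (f1 - 2 * f0 + f2) / ((h_hi - h2) * (h2 - h_lo) + 1e-30) if not boundary else np.nan
    se = float(np.sqrt(-1.0 / d2)) if d2 is not np.nan and np.isfinite(d2) and d2 < 0 else np.nan

    w = h2 * lam + (1 - h2)
    sigma2 = float((y2 / w).sum() / y2.size)
    return H2Estimate(
        h2=h2,
        se=se,
        lrt_p=lrt_p,
        boundary=bool(boundary),
        non_identifiable=bool(non_identifiable),
        loglik=ll_opt,
        sigma2_g=h2 * sigma2,
        sigma2_e=(1 - h2) * sigma2,
    )


class RemlHeritability(BaseEstimator):
    """Single-component REML heritability as a fit-shaped estimator.

    ``fit(grm, y)`` sets ``h2_``, ``se_``, ``lrt_p_``, ``estimate_``.
    """

    def __init__(self, covariates=None):
        self.covariates = covariates

    def fit(self, grm: GrmMatrix, y, sample_weight=None):
        est = reml_h2(np.asarray(y, dtype=float), grm, self.covariates)
        self.estimate_ = est
        self.h2_ = est.h2
        self.se_ = est.se
        self.lrt_p_ = est.lrt_p
        return self


# ---------------------------------------------------------------------------
# LD scores and stratified regression


def ld_scores(
    dosages: np.ndarray,
    positions: np.ndarray,
    annotations: dict[str, np.ndarray],
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Annotation-partitioned LD scores.

    l_{j,c} = sum over SNPs k within ``window`` bp of j that belong to c of
    the adjusted r2(j,k) = r2 - (1 - r2)/(n - 2). Positions must be sorted.
    """
    X = np.asarray(dosages, dtype=float)
    n, m = X.shape
    positions = np.asarray(positions, dtype=np.int64)
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    if positions.max() - positions.min() <= window and m > 1:
        pass  # whole-chromosome window is fine
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Z = (X - X.mean(axis=0)) / sd_safe
    names = list(annotations)
    member = np.column_stack([np.asarray(annotations[c], dtype=bool) for c in names])
    out = np.zeros((m, len(names)))
    lo = 0
    hi = 0
    for j in range(m):
        while positions[j] - positions[lo] > window:
            lo += 1
        while hi < m and positions[hi] - positions[j] <= window:
            hi += 1
        idx = np.arange(lo, hi)
        r = Z[:, idx].T @ Z[:, j] / n
        r2 = r**2
        r2_adj = r2 - (1.0 - r2) / (n - 2)
        r2_adj[sd[idx] == 0] = 0.0
        if sd[j] == 0:
            continue
        for c in range(len(names)):
            out[j, c] = float(r2_adj[member[idx, c]].sum())
    df = pd.DataFrame(out, columns=names)
    df.attrs["window"] = window
    return df


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    return np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)[0]


def stratified_regression(
    chisq: np.ndarray,
    ld_table: pd.DataFrame,
    n_gwas: float,
    annotations: dict[str, np.ndarray],
    n_blocks: int = 20,
    weights: np.ndarray | None = None,
) -> PartitionedH2Result:
    """Stratified LD-score regression with block-jackknife uncertainty.

    Fits chisq_j = intercept + N * sum_c tau_c l_{j,c} by (weighted) least
    squares. The heritability attributed to annotation c is the per-SNP
    contribution summed over its members, h2_c = sum_{j in c} sum_{c'}
    tau_{c'} a_{j,c'}; enrichment is (h2_c / h2_total) / (M_c / M).
    Standard errors come from a delete-one jackknife over ``n_blocks``
    contiguous SNP blocks.
    """
    chisq = np.asarray(chisq, dtype=float)
    m = chisq.size
    names = list(ld_table.columns)
    L = ld_table.to_numpy(dtype=float)
    member = np.column_stack([np.asarray(annotations[c], dtype=bool) for c in names])
    X = np.column_stack([np.ones(m), n_gwas * L])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"collinear annotation LD scores among {names}")
    if weights is None:
        weights = 1.0 / np.maximum(L.max(axis=1), 1.0)

    def estimates(mask: np.ndarray):
        beta = _wls(X[mask], chisq[mask], weights[mask])
        tau = beta[1:]
        # per-SNP heritability over the full SNP panel
        per_snp = member.astype(float) @ tau
        h2_tot = float(per_snp.sum())
        h2_c = np.array([float(per_snp[member[:, c]].sum()) for c in range(len(names))])
        prop = member.mean(axis=0)
        share = h2_c / h2_tot if h2_tot != 0 else np.full(len(names), np.nan)
        enr = share / prop
        return beta[0], tau, h2_c, share, enr

    intercept, tau, h2_c, share, enr = estimates(np.ones(m, dtype=bool))

    blocks = np.array_split(np.arange(m), n_blocks)
    taus, enrs = [], []
    for b in blocks:
        mask = np.ones(m, dtype=bool)
        mask[b] = False
        _, t_b, _, _, e_b = estimates(mask)
        taus.append(t_b)
        enrs.append(e_b)
    taus = np.array(taus)
    enrs = np.array(enrs)
    g = len(blocks)
    tau_se = np.sqrt((g - 1) / g * ((taus - taus.mean(axis=0)) ** 2).sum(axis=0))
    enr_se = np.sqrt((g - 1) / g * ((enrs - enrs.mean(axis=0)) ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(enr_se > 0, (enr - 1.0) / enr_se, 0.0)
    enr_p = 2.0 * stats.norm.sf(np.abs(z))

    per_snp = member.astype(float) @ tau
    return PartitionedH2Result(
        annotations=names,
        tau=tau,
        tau_se=tau_se,
        h2_share=share,
        snp_proportion=member.mean(axis=0),
        enrichment=enr,
        enrichment_se=enr_se,
        enrichment_p=enr_p,
        intercept=float(intercept),
        h2_total=float(per_snp.sum()),
    )


class StratifiedLdRegression(BaseEstimator):
    """Stratified LD-score regression as a fit-shaped estimator.

    ``fit(ld_table, chisq)`` sets ``tau_``, ``enrichment_``, ``result_``.
    """

    def __init__(self, n_gwas: float = 50_000, annotations=None, n_blocks: int = 20):
        self.n_gwas = n_gwas
        self.annotations = annotations
        self.n_blocks = n_blocks

    def fit(self, ld_table: pd.DataFrame, chisq, y=None):
        res = stratified_regression(
            np.asarray(chisq, dtype=float),
            ld_table,
            n_gwas=self.n_gwas,
            annotations=self.annotations,
            n_blocks=self.n_blocks,
        )
        self.result_ = res
        self.tau_ = res.tau
        self.enrichment_ = res.enrichment
        self.intercept_ = res.intercept
        return self
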