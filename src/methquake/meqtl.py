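"""Windowed SNP-cytosine association scanning.

The scan regresses smoothed methylation fractions on alternate-allele
dosage plus a fixed covariate matrix (ordinary least squares), applies a
genome-wide FDR-equivalent p-value cutoff, and summarizes significant
sites per SNP. An index-SNP mode tests every site on a chromosome and
labels pairs cis/trans by distance; an interaction mode tests a
genotype x modifier product term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "PairSkipped",
    "FitResult",
    "enumerate_cis_pairs",
    "fit_pair",
    "interaction_fit",
    "MeQtlScanner",
    "scan",
    "index_snp_scan",
    "interaction_scan",
    "fdr_pvalue_cutoff",
    "bh_qvalues",
    "summarize_snp",
]


class PairSkipped(Exception):
    """A pair could not be fit; ``.code`` states why."""

    def __init__(self, code: str):
        super().__init__(code)
        self.code = code


@dataclass
class FitResult:
    slope: float
    se: float
    t: float
    df: int
    p: float


# ---------------------------------------------------------------------------
# pair enumeration


def enumerate_cis_pairs(snps, sites: pd.DataFrame, window: int = 20_000):
    """Yield (snp index, site index) with matching chromosome and
    |pos difference| <= window, each pair exactly once, via a two-pointer
    sweep over position-sorted inputs."""
    site_chrom = sites["chrom"].to_numpy()
    site_pos = sites["pos"].to_numpy()
    for chrom in pd.unique(snps.chrom):
        snp_idx = np.flatnonzero(snps.chrom == chrom)
        s_idx = np.flatnonzero(site_chrom == chrom)
        if snp_idx.size == 0 or s_idx.size == 0:
            continue
        spos = site_pos[s_idx]
        lo = 0
        for j in snp_idx:
            p = snps.pos[j]
            while lo < s_idx.size and spos[lo] < p - window:
                lo += 1
            k = lo
            while k < s_idx.size and spos[k] <= p + window:
                yield int(j), int(s_idx[k])
                k += 1


# ---------------------------------------------------------------------------
# single-pair fits


def _ols_tstat(X: np.ndarray, y: np.ndarray, coef_idx: int) -> FitResult:
    """OLS of y on X; t-test of the coefficient at ``coef_idx``."""
    n, k = X.shape
    df = n - k
    if df < 1:
        raise PairSkipped("insufficient_df")
    if np.ptp(y) == 0:  # constant response: zero slope by construction
        return FitResult(slope=0.0, se=0.0, t=0.0, df=df, p=1.0)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        raise PairSkipped("collinear_design")
    resid = y - X @ beta
    rss = float(resid @ resid)
    xtx_inv = np.linalg.inv(X.T @ X)
    sigma2 = rss / df
    se = float(np.sqrt(max(sigma2 * xtx_inv[coef_idx, coef_idx], 0.0)))
    slope = float(beta[coef_idx])
    if se == 0.0:
        t = 0.0 if slope == 0.0 else np.inf * np.sign(slope)
    else:
        t = slope / se
    p = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    if slope == 0.0 and se == 0.0:
        p = 1.0
    return FitResult(slope=slope, se=se, t=float(t), df=df, p=min(p, 1.0))


def _complete_cases(dosage, *arrays):
    mask = ~np.isnan(np.asarray(dosage, dtype=float))
    for a in arrays:
        if a is not None:
            mask &= ~np.isnan(np.asarray(a, dtype=float)).reshape(len(mask), -1).any(axis=1)
    return mask


def fit_pair(dosage, meth, covariates=None) -> FitResult:
    """OLS of methylation on [intercept, dosage, covariates].

    Missing dosages are dropped pairwise (complete-case). A dosage constant
    after deletion raises :class:`PairSkipped`.
    """
    dosage = np.asarray(dosage, dtype=float)
    meth = np.asarray(meth, dtype=float)
    mask = _complete_cases(dosage, meth, covariates)
    d, y = dosage[mask], meth[mask]
    if np.ptp(d) == 0:
        raise PairSkipped("constant_dosage")
    cols = [np.ones(d.size), d]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)[mask]
        cols.append(C.reshape(d.size, -1))
    X = np.column_stack(cols)
    return _ols_tstat(X, y, coef_idx=1)


def interaction_fit(dosage, meth, modifier, covariates=None) -> FitResult:
    """OLS of methylation on [intercept, dosage, modifier, dosage*modifier,
    covariates]; returns the t-test of the product term."""
    dosage = np.asarray(dosage, dtype=float)
    modifier = np.asarray(modifier, dtype=float)
    if np.ptp(modifier[~np.isnan(modifier)]) == 0:
        raise ValueError("modifier is constant")
    meth = np.asarray(meth, dtype=float)
    mask = _complete_cases(dosage, meth, modifier, covariates)
    d, y, mod = dosage[mask], meth[mask], modifier[mask]
    if np.ptp(d) == 0:
        raise PairSkipped("constant_dosage")
    cols = [np.ones(d.size), d, mod, d * mod]
    if covariates is not None:
        cols.append(np.asarray(covariates, dtype=float)[mask].reshape(d.size, -1))
    X = np.column_stack(cols)
    return _ols_tstat(X, y, coef_idx=3)


# ---------------------------------------------------------------------------
# FDR machinery


def fdr_pvalue_cutoff(pvals, m_total: int | None = None, q_level: float = 0.01):
    """Largest p whose BH-adjusted value is <= q_level.

    ``m_total`` is the full number of tests performed, which may exceed
    ``len(pvals)`` when only small p-values were recorded (the unsaved ones
    count as non-discoveries). Returns None when nothing qualifies.
    """
    p = np.sort(np.asarray(pvals, dtype=float))
    if p.size == 0:
        return None
    m = int(m_total) if m_total is not None else p.size
    if m < p.size:
        raise ValueError("m_total smaller than number of recorded p-values")
    ranks = np.arange(1, p.size + 1)
    ok = p <= q_level * ranks / m
    if not ok.any():
        return None
    return float(p[np.flatnonzero(ok)[-1]])


def bh_qvalues(pvals, m_total: int | None = None) -> np.ndarray:
    """BH step-up adjusted values; supports an implied total test count
    larger than the recorded vector (all implied p assumed larger)."""
    p = np.asarray(pvals, dtype=float)
    m = int(m_total) if m_total is not None else p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(q)
    out[order] = np.minimum(q, 1.0)
    return out


# ---------------------------------------------------------------------------
# scanning


def _orthonormal_covariate_basis(covariates, n: int) -> np.ndarray:
    """Orthonormal basis Q of span{intercept, covariates} (n x r)."""
    if covariates is None:
        C = np.ones((n, 1))
    else:
        C = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    Q, R = np.linalg.qr(C)
    keep = np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(R).max())
    return Q[:, keep]


class MeQtlScanner(BaseEstimator):
    """Cis meQTL scan as a fit-shaped estimator.

    Parameters mirror the study defaults: a 20 kb window, covariate-adjusted
    OLS per pair, and a scan-wide BH p-value cutoff at FDR ``q_level``.

    After ``fit(genotypes, methylome)``:
    ``pairs_`` — DataFrame of kept pairs (p <= p_keep) with slope/se/t/p/q;
    ``n_tests_`` — total pairs tested; ``fdr_cutoff_`` — p-value equivalent
    to the requested FDR (None when nothing passes); ``skipped_`` — per-code
    counts of pairs that could not be fit.
    """

    def __init__(
        self,
        window: int = 20_000,
        p_keep: float = 1.0,
        q_level: float = 0.01,
        covariates=None,
        cis_window: int | None = None,
    ):
        self.window = window
        self.p_keep = p_keep
        self.q_level = q_level
        self.covariates = covariates
        self.cis_window = cis_window

    def fit(self, genotypes, methylome, y=None):
        values = methylome.smoothed if methylome.smoothed is not None else methylome.fractions
        self.pairs_ = scan_frame(
            genotypes,
            methylome.sites,
            values,
            covariates=self.covariates,
            window=self.window,
            p_keep=self.p_keep,
            cis_window=self.cis_window,
        )
        self.n_tests_ = self.pairs_.attrs["n_tests"]
        self.skipped_ = self.pairs_.attrs["skipped"]
        kept = self.pairs_["p"].to_numpy()
        self.fdr_cutoff_ = fdr_pvalue_cutoff(kept, m_total=self.n_tests_, q_level=self.q_level)
        if len(self.pairs_):
            self.pairs_["q"] = bh_qvalues(kept, m_total=self.n_tests_)
        else:
            self.pairs_["q"] = np.array([], dtype=float)
        return self

    @property
    def significant_(self) -> pd.DataFrame:
        if self.fdr_cutoff_ is None:
            return self.pairs_.iloc[0:0]
        return self.pairs_[self.pairs_["p"] <= self.fdr_cutoff_]


def scan_frame(
    genotypes,
    sites: pd.DataFrame,
    values: np.ndarray,
    covariates=None,
    window: int = 20_000,
    p_keep: float = 1.0,
    snp_subset=None,
    all_sites: bool = False,
    genome_wide: bool = False,
    cis_window: int | None = None,
) -> pd.DataFrame:
    """Vectorized scan over cis pairs (or all same-chromosome sites).

    Uses Frisch-Waugh-Lovell: methylation and dosage are residualized
    against [intercept, covariates] once, after which per-pair slope, SE
    and t match the full OLS exactly. SNPs with missing dosages fall back
    to the per-pair complete-case fit.
    """
    n = values.shape[1]
    Q = _orthonormal_covariate_basis(covariates, n)
    r = Q.shape[1]
    df = n - r - 1
    V = values.T  # samples x sites
    Vr = V - Q @ (Q.T @ V)  # residualized methylation
    vss = (Vr**2).sum(axis=0)

    site_pos = sites["pos"].to_numpy()
    site_chrom = sites["chrom"].to_numpy()
    site_context = sites["context"].to_numpy() if "context" in sites else np.repeat("CpG", len(sites))

    rows = []
    skipped: dict[str, int] = {}
    n_tests = 0
    snp_iter = range(genotypes.n_snps) if snp_subset is None else snp_subset
    for j in snp_iter:
        chrom_mask = site_chrom == genotypes.chrom[j]
        if all_sites:
            sidx = (
                np.arange(len(sites)) if genome_wide else np.flatnonzero(chrom_mask)
            )
        else:
            dist_ok = np.abs(site_pos - genotypes.pos[j]) <= window
            sidx = np.flatnonzero(chrom_mask & dist_ok)
        if sidx.size == 0:
            continue
        d = genotypes.dosage[:, j]
        if np.isnan(d).any():
            # pairwise complete-case per pair
            for s in sidx:
                n_tests += 1
                try:
                    res = fit_pair(d, values[s], covariates)
                except PairSkipped as exc:
                    skipped[exc.code] = skipped.get(exc.code, 0) + 1
                    continue
                if res.p <= p_keep:
                    rows.append((j, int(s), res.slope, res.se, res.t, res.df, res.p))
            continue
        if np.ptp(d) == 0:
            skipped["constant_dosage"] = skipped.get("constant_dosage", 0) + sidx.size
            n_tests += sidx.size
            continue
        dr = d - Q @ (Q.T @ d)
        dss = float(dr @ dr)
        n_tests += sidx.size
        num = Vr[:, sidx].T @ dr
        slope = num / dss
        rss = vss[sidx] - slope**2 * dss
        rss = np.maximum(rss, 0.0)
        sigma2 = rss / df
        se = np.sqrt(sigma2 / dss)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, slope / se, np.where(slope == 0, 0.0, np.inf))
        p = np.where(np.isfinite(t), 2.0 * stats.t.sf(np.abs(t), df), 0.0)
        p = np.where((slope == 0) & (se == 0), 1.0, p)
        # constant methylation columns: only numerical dust remains after
        # residualization; report a null result rather than dust ratios
        const = np.ptp(values[sidx], axis=1) == 0
        slope, t = np.where(const, 0.0, slope), np.where(const, 0.0, t)
        se, p = np.where(const, 0.0, se), np.where(const, 1.0, p)
        keep = p <= p_keep
        for s, sl, e, tt, pp in zip(sidx[keep], slope[keep], se[keep], t[keep], p[keep]):
            rows.append((j, int(s), float(sl), float(e), float(tt), df, float(pp)))

    out = pd.DataFrame(
        rows, columns=["snp_idx", "site_idx", "slope", "se", "t", "df", "p"]
    )
    if len(out):
        out["snp"] = [genotypes.snp_ids[j] for j in out["snp_idx"]]
        out["chrom"] = site_chrom[out["site_idx"]]
        out["pos"] = site_pos[out["site_idx"]]
        out["context"] = site_context[out["site_idx"]]
        snp_pos = genotypes.pos[out["snp_idx"].to_numpy()]
        snp_chrom = genotypes.chrom[out["snp_idx"].to_numpy()]
        cw = cis_window if cis_window is not None else window
        same = snp_chrom == out["chrom"].to_numpy()
        near = np.abs(snp_pos - out["pos"].to_numpy()) <= cw
        out["cis_flag"] = np.where(same & near, "cis", "trans")
        out = out.sort_values(["chrom", "pos", "snp"], kind="mergesort").reset_index(drop=True)
    else:
        for c in ("snp", "chrom", "pos", "context", "cis_flag"):
            out[c] = []
    out.attrs["n_tests"] = n_tests
    out.attrs["skipped"] = skipped
    return out


def scan(genotypes, methylome, covariates=None, window: int = 20_000, p_keep: float = 1.0,
         q_level: float = 0.01) -> MeQtlScanner:
    """Thin functional wrapper: fit a :class:`MeQtlScanner` and return it."""
    return MeQtlScanner(
        window=window, p_keep=p_keep, q_level=q_level, covariates=covariates
    ).fit(genotypes, methylome)


def index_snp_scan(
    genotypes,
    methylome,
    snp_indices,
    covariates=None,
    cis_window: int = 250_000,
    genome_wide: bool = False,
) -> pd.DataFrame:
    """Test the given index SNPs against every site on their chromosome
    (or the whole genome), keeping all p-values, with cis/trans labels at
    ``cis_window``."""
    values = methylome.smoothed if methylome.smoothed is not None else methylome.fractions
    return scan_frame(
        genotypes,
        methylome.sites,
        values,
        covariates=covariates,
        snp_subset=list(snp_indices),
        all_sites=True,
        genome_wide=genome_wide,
        cis_window=cis_window,
    )


def interaction_scan(
    genotypes,
    methylome,
    modifier,
    covariates=None,
    window: int = 20_000,
    p_keep: float = 1.0,
) -> pd.DataFrame:
    """Genotype x modifier interaction scan over cis pairs.

    For each pair fits meth ~ intercept + dosage + modifier +
    dosage*modifier + covariates and reports the product-term t and p.
    """
    modifier = np.asarray(modifier, dtype=float)
    if np.ptp(modifier) == 0:
        raise ValueError("modifier is constant")
    values = methylome.smoothed if methylome.smoothed is not None else methylome.fractions
    n = values.shape[1]
    sites = methylome.sites
    site_pos = sites["pos"].to_numpy()
    site_chrom = sites["chrom"].to_numpy()
    rows = []
    skipped: dict[str, int] = {}
    for j in range(genotypes.n_snps):
        sidx = np.flatnonzero(
            (site_chrom == genotypes.chrom[j])
            & (np.abs(site_pos - genotypes.pos[j]) <= window)
        )
        if sidx.size == 0:
            continue
        d = genotypes.dosage[:, j]
        if np.isnan(d).any():
            for s in sidx:
                try:
                    res = interaction_fit(d, values[s], modifier, covariates)
                except PairSkipped as exc:
                    skipped[exc.code] = skipped.get(exc.code, 0) + 1
                    continue
                if res.p <= p_keep:
                    rows.append((j, int(s), res.slope, res.se, res.t, res.df, res.p))
            continue
        if np.ptp(d) == 0:
            skipped["constant_dosage"] = skipped.get("constant_dosage", 0) + sidx.size
            continue
        base_cols = [np.ones(n), d, modifier]
        if covariates is not None:
            base_cols.append(np.asarray(covariates, dtype=float).reshape(n, -1))
        B = np.column_stack(base_cols)
        Qb, Rb = np.linalg.qr(B)
        keep_cols = np.abs(np.diag(Rb)) > 1e-10 * max(1.0, np.abs(Rb).max())
        Qb = Qb[:, keep_cols]
        prod = d * modifier
        pr = prod - Qb @ (Qb.T @ prod)
        pss = float(pr @ pr)
        df = n - Qb.shape[1] - 1
        if pss < 1e-12 or df < 1:
            skipped["collinear_design"] = skipped.get("collinear_design", 0) + sidx.size
            continue
        V = values[sidx].T
        Vr = V - Qb @ (Qb.T @ V)
        num = Vr.T @ pr
        slope = num / pss
        rss = np.maximum((Vr**2).sum(axis=0) - slope**2 * pss, 0.0)
        se = np.sqrt(rss / df / pss)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, slope / se, np.where(slope == 0, 0.0, np.inf))
        p = np.where(np.isfinite(t), 2.0 * stats.t.sf(np.abs(t), df), 0.0)
        p = np.where((slope == 0) & (se == 0), 1.0, p)
        const = np.ptp(values[sidx], axis=1) == 0
        slope, t = np.where(const, 0.0, slope), np.where(const, 0.0, t)
        se, p = np.where(const, 0.0, se), np.where(const, 1.0, p)
        for s, sl, e, tt, pp in zip(sidx, slope, se, t, p):
            if pp <= p_keep:
                rows.append((j, int(s), float(sl), float(e), float(tt), df, float(pp)))
    out = pd.DataFrame(
        rows, columns=["snp_idx", "site_idx", "slope", "se", "t", "df", "p"]
    )
    out.attrs["skipped"] = skipped
    return out


def summarize_snp(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP summaries of significant pairs: site count, bp span of
    significant sites, and mean |slope|."""
    if len(pairs) == 0:
        return pd.DataFrame(columns=["snp", "n_sites", "width_bp", "mean_abs_slope"])
    g = pairs.groupby("snp", sort=False)
    out = pd.DataFrame(
        {
            "n_sites": g.size(),
            "width_bp": g["pos"].max() - g["pos"].min(),
            "mean_abs_slope": g["slope"].apply(lambda s: float(np.abs(s).mean())),
        }
    ).reset_index()
    return out
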