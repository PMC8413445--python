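"""Storey pi0/pi1 estimation for cross-dataset replication sharing.

Discovery-significant SNP-site pairs are re-evaluated in a second dataset;
the fraction of true associations among them is estimated as
pi1 = 1 - pi0, where pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is
smoothed over a lambda grid and read off at the largest lambda.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Pi1Estimate", "storey_pi0", "pi1_sharing"]


@dataclass
class Pi1Estimate:
    pi0: float
    pi1: float
    lambda_grid: np.ndarray
    method: str  # "smoother" or "fixed-lambda"
    n_pvalues: int
    raw_pi0: float | None = None  # pre-clamp value, recorded when out of range
    n_unmatched: int = 0


def storey_pi0(
    pvals,
    lambda_grid: np.ndarray | None = None,
    method: str = "smoother",
) -> Pi1Estimate:
    """Estimate the true-null proportion pi0 from a p-value vector.

    ``smoother``: raw estimates pi0(lambda) over the grid are smoothed by a
    least-squares cubic fit and evaluated at the largest lambda (the
    convention of the q-value package's df=3 spline smoother).
    ``fixed-lambda``: the raw estimate at lambda = 0.5, for very small m.
    Estimates are clamped to [0, 1]; the raw value is kept in the record.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size < 100:
        warnings.warn("fewer than 100 p-values; pi0 estimate may be unstable", stacklevel=2)
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.951, 0.05)
    lam = np.asarray(lambda_grid, dtype=float)
    m = p.size
    raw = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    if method == "fixed-lambda":
        l0 = lam[np.argmin(np.abs(lam - 0.5))]
        pi0_raw = float((p > l0).sum() / (m * (1.0 - l0)))
    elif method == "smoother":
        coef = np.polynomial.polynomial.polyfit(lam, raw, deg=min(3, lam.size - 1))
        pi0_raw = float(np.polynomial.polynomial.polyval(lam.max(), coef))
    else:
        raise ValueError(f"unknown method {method!r}")
    pi0 = min(1.0, max(0.0, pi0_raw))
    return Pi1Estimate(
        pi0=pi0,
        pi1=1.0 - pi0,
        lambda_grid=lam,
        method=method,
        n_pvalues=m,
        raw_pi0=pi0_raw if not (0.0 <= pi0_raw <= 1.0) else None,
    )


def pi1_sharing(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    keys: tuple[str, str] = ("snp", "site_idx"),
    p_col: str = "p",
    **kwargs,
) -> Pi1Estimate:
    """pi1 of replication p-values at discovery-significant pairs.

    ``discovery`` holds the significant pairs of the main analysis;
    ``replication`` holds statistics for (at least) the intersecting pairs.
    All matched replication p-values enter the estimate regardless of their
    own significance; unmatched pairs are counted in ``n_unmatched``.
    """
    left = discovery[list(keys)].drop_duplicates()
    merged = left.merge(replication[[*keys, p_col]], on=list(keys), how="left")
    matched = merged[p_col].dropna().to_numpy()
    if matched.size == 0:
        raise ValueError("no discovery pairs found in the replication dataset")
    est = storey_pi0(matched, **kwargs)
    est.n_unmatched = int(len(merged) - matched.size)
    return est
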