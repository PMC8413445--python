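"""Methylation mediation of expression QTLs by coefficient attenuation.

For SNPs that are both eQTLs and meQTLs, and CpG-feature combinations with
|cor| > 0.3 between expression and methylation, two nested models are fit:
E ~ G + C and E ~ G + M + C. The ratio of the genotype coefficients
(adjusted / marginal) is the proportion of the effect retained; a retained
proportion below 0.75 (a >25% reduction) counts as evidence of mediation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MediationRecord",
    "select_triplets",
    "mediation_fit",
    "summarize_mediation",
]

PROP_THRESHOLD = 0.75
BETA_FLOOR = 1e-6  # in standardized units; |beta1| below this is "unstable"


@dataclass
class MediationRecord:
    snp: str | int
    site: int
    feature: str
    level: str
    cor_em: float
    beta_marginal: float
    beta_adjusted: float
    prop_retained: float
    mediated: bool
    unstable: bool = False


def select_triplets(
    eqtl_snps,
    meqtl_pairs: pd.DataFrame,
    expression: pd.DataFrame,
    methylation: np.ndarray,
    cor_threshold: float = 0.3,
    signed: bool = False,
) -> pd.DataFrame:
    """(SNP, CpG, feature) triplets passing the expression-methylation
    correlation gate.

    ``eqtl_snps`` are SNP labels significant in an external eQTL map;
    ``meqtl_pairs`` holds significant meQTL pairs (columns snp, site_idx);
    ``expression`` is features x samples with a ``level`` column;
    ``methylation`` is sites x samples on the same sample set. The gate is
    |Pearson r| > cor_threshold (signed r > threshold when ``signed``).
    """
    expr_values = expression.drop(columns=["level"]).to_numpy(dtype=float)
    if expr_values.shape[1] != methylation.shape[1]:
        raise ValueError("expression and methylation share no common sample set")
    shared = meqtl_pairs[meqtl_pairs["snp"].isin(set(eqtl_snps))]
    rows = []
    for snp, grp in shared.groupby("snp", sort=False):
        for site in grp["site_idx"].unique():
            m = methylation[int(site)]
            if np.std(m) == 0:
                continue
            for fi, feature in enumerate(expression.index):
                e = expr_values[fi]
                if np.std(e) == 0:
                    continue
                r = float(np.corrcoef(e, m)[0, 1])
                passed = r > cor_threshold if signed else abs(r) > cor_threshold
                if passed:
                    rows.append(
                        {
                            "snp": snp,
                            "site_idx": int(site),
                            "feature": feature,
                            "level": expression.loc[feature, "level"],
                            "cor_em": r,
                        }
                    )
    return pd.DataFrame(rows, columns=["snp", "site_idx", "feature", "level", "cor_em"])


def mediation_fit(
    expression: np.ndarray,
    dosage: np.ndarray,
    methylation: np.ndarray,
    covariates: np.ndarray | None = None,
    snp="",
    site: int = -1,
    feature: str = "",
    level: str = "gene",
) -> MediationRecord:
    """Two nested OLS fits sharing covariates and sample set.

    beta_marginal: genotype coefficient of E ~ G + C; beta_adjusted: of
    E ~ G + M + C. prop_retained = beta_adjusted / beta_marginal. Records
    are flagged unstable (and never counted as mediated) when the marginal
    coefficient is within the floor of zero in standardized units, or the
    ratio flips sign.
    """
    e = np.asarray(expression, dtype=float)
    g = np.asarray(dosage, dtype=float)
    m = np.asarray(methylation, dtype=float)
    if np.ptp(g) == 0:
        raise ValueError("constant dosage")
    n = e.size
    cols = [np.ones(n), g]
    if covariates is not None:
        cols.append(np.asarray(covariates, dtype=float).reshape(n, -1))
    X1 = np.column_stack(cols)
    X2 = np.column_stack([X1[:, :2], m, X1[:, 2:]])
    for X in (X1, X2):
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise np.linalg.LinAlgError("singular mediation design")
    b1 = np.linalg.lstsq(X1, e, rcond=None)[0][1]
    b2 = np.linalg.lstsq(X2, e, rcond=None)[0][1]
    e_sd = np.std(e)
    g_sd = np.std(g)
    b1_std = b1 * g_sd / e_sd if e_sd > 0 else 0.0
    unstable = abs(b1_std) < BETA_FLOOR
    prop = b2 / b1 if b1 != 0 else np.nan
    # material sign flips are unstable; a slightly negative ratio is the
    # noise signature of full mediation (beta_adjusted ~ 0), not a flip
    if not unstable and np.isfinite(prop) and prop < -0.1:
        unstable = True
    r = float(np.corrcoef(e, m)[0, 1]) if np.std(m) > 0 and e_sd > 0 else 0.0
    mediated = bool(not unstable and np.isfinite(prop) and prop < PROP_THRESHOLD)
    return MediationRecord(
        snp=snp,
        site=site,
        feature=feature,
        level=level,
        cor_em=r,
        beta_marginal=float(b1),
        beta_adjusted=float(b2),
        prop_retained=float(prop),
        mediated=mediated,
        unstable=bool(unstable),
    )


def summarize_mediation(records: list[MediationRecord]) -> pd.DataFrame:
    """Per-feature-level median mediated proportion (1 - prop_retained among
    mediated records) and counts."""
    df = pd.DataFrame([r.__dict__ for r in records])
    if df.empty:
        return pd.DataFrame(columns=["level", "n_mediated", "median_mediation"])
    med = df[df["mediated"]]
    if med.empty:
        return pd.DataFrame(columns=["level", "n_mediated", "median_mediation"])
    g = med.groupby("level", sort=False)
    return pd.DataFrame(
        {
            "n_mediated": g.size(),
            "median_mediation": g["prop_retained"].apply(lambda s: float((1.0 - s).median())),
        }
    ).reset_index()
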