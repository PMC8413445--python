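"""Methylome and genotype I/O, site filters, and local smoothing.

Coordinate conventions: every site position in memory is 1-based; BED input
and output are 0-based half-open. Conversions are centralized in
:func:`bed_interval_covers` / :func:`sites_to_bed`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

SITE_COLUMNS = ["chrom", "pos", "context", "strand"]

__all__ = [
    "MethylomeMatrix",
    "GenotypeSet",
    "read_methylome",
    "write_methylome",
    "filter_cpg",
    "filter_cph",
    "exclude_blacklist",
    "read_bed",
    "LocalSmoother",
    "smooth_sample",
    "smooth_methylome",
    "read_genotypes",
    "hwe_pvalue",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class MethylomeMatrix:
    """Per-site methylated/total read counts (sites x samples).

    ``sites`` is a DataFrame with columns chrom, pos (1-based), context
    ("CpG"/"CpH") and strand; rows are sorted by (chrom, pos). ``smoothed``
    holds fractions in [0, 1] once smoothing has run.
    """

    sites: pd.DataFrame
    samples: list[str]
    methylated: np.ndarray
    coverage: np.ndarray
    smoothed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        n_sites, n_samples = len(self.sites), len(self.samples)
        for name in ("methylated", "coverage"):
            mat = np.asarray(getattr(self, name))
            if mat.shape != (n_sites, n_samples):
                raise ValueError(
                    f"{name} has shape {mat.shape}, expected {(n_sites, n_samples)}"
                )
            setattr(self, name, mat)
        if np.any(self.methylated > self.coverage):
            raise ValueError("methylated count exceeds coverage")
        if np.any(self.methylated < 0) or np.any(self.coverage < 0):
            raise ValueError("negative counts")
        if self.smoothed is not None:
            self.smoothed = np.asarray(self.smoothed, dtype=float)
            if self.smoothed.shape != (n_sites, n_samples):
                raise ValueError("smoothed matrix has wrong shape")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def fractions(self) -> np.ndarray:
        """Raw methylated/coverage with NaN where coverage is zero."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.coverage > 0, self.methylated / np.maximum(self.coverage, 1), np.nan)

    def take_sites(self, idx) -> "MethylomeMatrix":
        idx = np.asarray(idx)
        return MethylomeMatrix(
            sites=self.sites.iloc[idx],
            samples=list(self.samples),
            methylated=self.methylated[idx],
            coverage=self.coverage[idx],
            smoothed=None if self.smoothed is None else self.smoothed[idx],
        )


@dataclass
class GenotypeSet:
    """Biallelic SNP dosages (samples x SNPs) with per-SNP QC metadata."""

    snp_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    dosage: np.ndarray  # float, NaN = missing
    samples: list[str]
    maf: np.ndarray = field(default=None)
    missingness: np.ndarray = field(default=None)
    hwe_p: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom)
        self.dosage = np.asarray(self.dosage, dtype=float)
        n_samples, n_snps = len(self.samples), len(self.snp_ids)
        if self.dosage.shape != (n_samples, n_snps):
            raise ValueError("dosage must be samples x SNPs")
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0/1/2 or missing")
        if self.maf is None:
            alt = np.nanmean(self.dosage, axis=0) / 2.0
            self.maf = np.minimum(alt, 1 - alt)
        if self.missingness is None:
            self.missingness = np.isnan(self.dosage).mean(axis=0)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def take_snps(self, idx) -> "GenotypeSet":
        idx = np.asarray(idx)
        return GenotypeSet(
            snp_ids=[self.snp_ids[i] for i in idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            dosage=self.dosage[:, idx],
            samples=list(self.samples),
            maf=self.maf[idx],
            missingness=self.missingness[idx],
            hwe_p=None if self.hwe_p is None else self.hwe_p[idx],
        )

    def take_samples(self, idx) -> "GenotypeSet":
        idx = np.asarray(idx)
        return GenotypeSet(
            snp_ids=list(self.snp_ids),
            chrom=self.chrom,
            pos=self.pos,
            dosage=self.dosage[idx],
            samples=[self.samples[i] for i in idx],
            maf=None,
            missingness=None,
            hwe_p=self.hwe_p,
        )


# ---------------------------------------------------------------------------
# Bismark-coverage-style I/O

_COV_COLS = ["chrom", "start", "end", "meth_pct", "methylated", "unmethylated"]


def write_methylome(m: MethylomeMatrix, paths: dict[str, str]) -> None:
    """Write one Bismark-coverage-style TSV per sample.

    Columns: chrom, pos, pos, methylation %, methylated count, unmethylated
    count, context. Percentages for zero-coverage sites are written as 0.
    """
    for j, sample in enumerate(m.samples):
        cov = m.coverage[:, j]
        meth = m.methylated[:, j]
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(cov > 0, 100.0 * meth / np.maximum(cov, 1), 0.0)
        df = pd.DataFrame(
            {
                "chrom": m.sites["chrom"],
                "start": m.sites["pos"],
                "end": m.sites["pos"],
                "meth_pct": np.round(pct, 6),
                "methylated": meth,
                "unmethylated": cov - meth,
                "context": m.sites["context"],
            }
        )
        df.to_csv(paths[sample], sep="\t", header=False, index=False)


def _read_one_coverage(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    if df.shape[1] == 6:
        df.columns = _COV_COLS
        df["context"] = "CpG"
    elif df.shape[1] == 7:
        df.columns = _COV_COLS + ["context"]
    else:
        raise ValueError(f"{path}: expected 6 or 7 columns, got {df.shape[1]}")
    bad = df["methylated"] < 0
    if bad.any():
        raise ValueError(f"{path}: negative methylated count at line {bad.idxmax() + 1}")
    if df.duplicated(subset=["chrom", "start", "context"]).any():
        line = int(df.duplicated(subset=["chrom", "start", "context"]).idxmax()) + 1
        raise ValueError(f"{path}: duplicate site at line {line}")
    return df


def read_methylome(paths: dict[str, str]) -> MethylomeMatrix:
    """Load per-sample count files into a single site-by-sample matrix.

    Site universes are unioned; a site absent from a sample's file gets
    coverage 0 in that sample. A methylated count exceeding coverage is a
    hard error naming the file and line.
    """
    frames = {s: _read_one_coverage(p) for s, p in paths.items()}
    for sample, df in frames.items():
        over = df["unmethylated"] < 0
        if over.any():
            raise ValueError(
                f"{paths[sample]}: methylated > coverage at line {int(over.idxmax()) + 1}"
            )
    samples = list(paths)
    universe = (
        pd.concat([df[["chrom", "start", "context"]] for df in frames.values()])
        .drop_duplicates()
        .sort_values(["chrom", "start"], kind="mergesort")
        .reset_index(drop=True)
    )
    key = pd.MultiIndex.from_frame(universe)
    n = len(universe)
    methylated = np.zeros((n, len(samples)), dtype=np.int64)
    coverage = np.zeros((n, len(samples)), dtype=np.int64)
    for j, sample in enumerate(samples):
        df = frames[sample]
        loc = key.get_indexer(pd.MultiIndex.from_frame(df[["chrom", "start", "context"]]))
        methylated[loc, j] = df["methylated"].to_numpy()
        coverage[loc, j] = (df["methylated"] + df["unmethylated"]).to_numpy()
    sites = pd.DataFrame(
        {
            "chrom": universe["chrom"],
            "pos": universe["start"].astype(np.int64),
            "context": universe["context"],
            "strand": "unknown",
        }
    )
    return MethylomeMatrix(sites=sites, samples=samples, methylated=methylated, coverage=coverage)


# ---------------------------------------------------------------------------
# site filters


def filter_cpg(m: MethylomeMatrix, min_cov: float = 3) -> MethylomeMatrix:
    """Retain CpG sites whose mean coverage across samples is >= min_cov.

    Non-CpG sites are dropped. Order is preserved; the filter is idempotent.
    """
    is_cpg = (m.sites["context"] == "CpG").to_numpy()
    keep = is_cpg & (m.coverage.mean(axis=1) >= min_cov)
    if not keep.any():
        warnings.warn("filter_cpg: no sites retained", stacklevel=2)
    return m.take_sites(np.flatnonzero(keep))


def filter_cph(m: MethylomeMatrix, min_cov: int = 4, min_nonzero_frac: float = 0.5) -> MethylomeMatrix:
    """Retain CpH sites with (coverage > 3 and methylated > 0) in at least
    ``min_nonzero_frac`` of samples; both conditions are evaluated jointly
    per sample."""
    is_cph = (m.sites["context"] == "CpH").to_numpy()
    ok = (m.coverage >= min_cov) & (m.methylated > 0)
    keep = is_cph & (ok.mean(axis=1) >= min_nonzero_frac)
    return m.take_sites(np.flatnonzero(keep))


def read_bed(path: str) -> pd.DataFrame:
    """Read BED3 (0-based half-open); malformed lines raise with line number."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed BED line {i}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed BED line {i}") from exc
            if end < start or start < 0:
                raise ValueError(f"{path}: malformed BED line {i}")
            rows.append((parts[0], start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def bed_interval_covers(pos_1based: int, start0: int, end0: int) -> bool:
    """True if a 0-based half-open interval covers a 1-based position."""
    return start0 < pos_1based <= end0


def exclude_blacklist(sites: pd.DataFrame, blacklist: pd.DataFrame) -> np.ndarray:
    """Boolean mask of sites NOT falling in any blacklist interval.

    ``sites`` uses 1-based positions; ``blacklist`` is BED (0-based
    half-open). Input order is preserved by the caller applying the mask.
    """
    keep = np.ones(len(sites), dtype=bool)
    if len(blacklist) == 0:
        return keep
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in blacklist.groupby("chrom"):
        ivs = [(s, e) for s, e in zip(grp["start"], grp["end"]) if e > s]
        trees[chrom] = IntervalTree.from_tuples(ivs) if ivs else IntervalTree()
    chroms = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    for i in range(len(sites)):
        tree = trees.get(chroms[i])
        # 1-based pos p corresponds to 0-based coordinate p-1
        if tree is not None and tree.overlaps_point(int(pos[i]) - 1):
            keep[i] = False
    return keep


# ---------------------------------------------------------------------------
# local smoothing


def _tricube(u: np.ndarray) -> np.ndarray:
    u = np.clip(np.abs(u), 0.0, 1.0)
    return (1.0 - u**3) ** 3


class _WindowPlan:
    """Precomputed smoothing geometry for one chromosome.

    The half-widths, flattened window membership and tricube distance
    weights depend only on positions, so they are shared across samples.
    """

    def __init__(self, positions: np.ndarray, min_sites: int, min_width: int):
        positions = np.asarray(positions, dtype=np.int64)
        if np.any(np.diff(positions) < 0):
            raise ValueError("positions must be sorted ascending")
        n = positions.size
        ns = min(min_sites, n)
        if n < min_sites:
            warnings.warn(
                "fewer sites than min_sites; window is the whole chromosome", stacklevel=2
            )
        # half-width = (ns-1)-th smallest non-self |distance|, i.e. the
        # smallest symmetric window holding >= ns sites; candidates are the
        # ns-1 nearest sites on each side
        p = positions.astype(float)
        if ns > 1:
            k = ns - 1
            D = np.full((n, 2 * k), np.inf)
            for off in range(1, k + 1):
                D[off:, off - 1] = p[off:] - p[:-off]
                D[:-off, k + off - 1] = p[off:] - p[:-off]
            h = np.partition(D, k - 1, axis=1)[:, k - 1]
            span = float(p[-1] - p[0]) if n > 1 else 0.0
            h = np.minimum(h, max(span, 1.0))
        else:
            h = np.zeros(n)
        self.h = np.maximum(h, min_width / 2.0)
        left = np.searchsorted(positions, positions - self.h, side="left")
        right = np.searchsorted(positions, positions + self.h, side="right")
        counts = right - left
        self.starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        self.idx = np.concatenate([np.arange(l, r) for l, r in zip(left, right)])
        x = p[self.idx] - np.repeat(p, counts)
        self.x = x
        self.tri = _tricube(x / np.repeat(np.maximum(self.h, 1.0), counts))
        self.positions = positions


def _plan_smooth(
    plan: _WindowPlan, frac: np.ndarray, coverage: np.ndarray, clip: bool = True
) -> np.ndarray:
    """Weighted local-linear fit at each site given a window plan."""
    w = plan.tri * coverage[plan.idx]
    y = frac[plan.idx]
    x = plan.x
    seg = plan.starts
    sw = np.add.reduceat(w, seg)
    swx = np.add.reduceat(w * x, seg)
    swy = np.add.reduceat(w * y, seg)
    swxx = np.add.reduceat(w * x * x, seg)
    swxy = np.add.reduceat(w * x * y, seg)
    with np.errstate(invalid="ignore", divide="ignore"):
        xbar = swx / sw
        ybar = swy / sw
        sxx = swxx - sw * xbar**2
        sxy = swxy - sw * xbar * ybar
        slope = np.where(sxx > 1e-12, sxy / np.where(sxx > 1e-12, sxx, 1.0), 0.0)
        fit = ybar - slope * xbar  # fitted value at the site itself (x = 0)
    out = np.clip(fit, 0.0, 1.0) if clip else fit
    # windows with no positive weight (isolated zero-coverage stretches):
    # fall back to the chromosome-wide mean fraction
    if np.isnan(out).any():
        total_cov = coverage.sum()
        fallback = float((frac * coverage).sum() / total_cov) if total_cov > 0 else 0.5
        out = np.where(np.isnan(out), fallback, out)
    return out


def smooth_sample(
    methylated: np.ndarray,
    coverage: np.ndarray,
    positions: np.ndarray,
    min_sites: int = 70,
    min_width: int = 2000,
) -> np.ndarray:
    """Coverage-weighted local-linear smoothing of methylation fractions.

    For each site, the smallest symmetric window around it containing at
    least ``min_sites`` sites and spanning at least ``min_width`` bp is
    selected; a weighted linear fit (tricube distance weights times read
    coverage) of the raw fractions on position yields the smoothed value,
    clipped to [0, 1]. Zero-coverage sites receive the local fitted value.
    """
    methylated = np.asarray(methylated, dtype=float)
    coverage = np.asarray(coverage, dtype=float)
    frac = np.where(coverage > 0, methylated / np.maximum(coverage, 1.0), 0.0)
    plan = _WindowPlan(np.asarray(positions, dtype=np.int64), min_sites, min_width)
    return _plan_smooth(plan, frac, coverage)


class LocalSmoother(BaseEstimator, TransformerMixin):
    """Per-sample local-linear smoother over genomic position.

    A scikit-learn style transformer: X is (samples x sites) of methylated
    counts paired with a coverage matrix of the same shape; ``transform``
    returns smoothed fractions. The smoother is stateless — ``fit`` only
    validates inputs.

    Parameters
    ----------
    positions : 1-based bp per site, sorted, single chromosome.
    min_sites : minimum number of sites per window.
    min_width : minimum window span in bp.
    """

    def __init__(self, positions=None, min_sites: int = 70, min_width: int = 2000):
        self.positions = positions
        self.min_sites = min_sites
        self.min_width = min_width

    def fit(self, X, y=None):
        X = np.asarray(X)
        if self.positions is None or len(self.positions) != X.shape[1]:
            raise ValueError("positions must match the number of sites (columns)")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X, coverage=None):
        if coverage is None:
            raise ValueError("coverage matrix required")
        X = np.asarray(X, dtype=float)
        coverage = np.asarray(coverage, dtype=float)
        out = np.empty_like(X)
        for i in range(X.shape[0]):
            out[i] = smooth_sample(
                X[i], coverage[i], self.positions, self.min_sites, self.min_width
            )
        return out


def smooth_methylome(m: MethylomeMatrix, min_sites: int = 70, min_width: int = 2000) -> MethylomeMatrix:
    """Smooth every sample per chromosome; returns a copy with ``smoothed`` set."""
    smoothed = np.empty(m.methylated.shape, dtype=float)
    for chrom, grp in m.sites.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        plan = _WindowPlan(grp["pos"].to_numpy(), min_sites, min_width)
        meth = m.methylated[idx].astype(float)
        cov = m.coverage[idx].astype(float)
        frac = np.where(cov > 0, meth / np.maximum(cov, 1.0), 0.0)
        for j in range(len(m.samples)):
            smoothed[idx, j] = _plan_smooth(plan, frac[:, j], cov[:, j])
    return replace(m, smoothed=smoothed)


# ---------------------------------------------------------------------------
# genotypes


def hwe_pvalue(n_ref: int, n_het: int, n_alt: int) -> float:
    """Hardy-Weinberg chi-square test (1 df) on genotype counts."""
    n = n_ref + n_het + n_alt
    if n == 0:
        return 1.0
    p = (2 * n_ref + n_het) / (2.0 * n)
    q = 1.0 - p
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_ref, n_het, n_alt], dtype=float)
    nz = exp > 0
    chi2 = ((obs[nz] - exp[nz]) ** 2 / exp[nz]).sum()
    return float(stats.chi2.sf(chi2, df=1))


def read_genotypes(
    vcf_path: str,
    maf_min: float = 0.05,
    miss_max: float = 0.10,
    hwe_p_min: float = 1e-6,
) -> GenotypeSet:
    """Read biallelic SNPs from a VCF into a dosage matrix with QC filters.

    Dosage is the alternate-allele count. SNPs failing MAF, missingness or
    Hardy-Weinberg filters are removed; multi-allelic records are skipped
    with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    ids, chroms, poss, rows, mafs, misses, hwes = [], [], [], [], [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gts = np.array(var.genotypes, dtype=object)
        dos = np.full(len(samples), np.nan)
        for i, g in enumerate(var.genotypes):
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                continue
            dos[i] = (a > 0) + (b > 0)
        miss = float(np.isnan(dos).mean())
        valid = dos[~np.isnan(dos)]
        if valid.size == 0:
            continue
        alt_f = valid.mean() / 2.0
        maf = min(alt_f, 1.0 - alt_f)
        counts = [int((valid == k).sum()) for k in (0, 1, 2)]
        hwe = hwe_pvalue(*counts)
        if maf <= maf_min or miss > miss_max or hwe <= hwe_p_min:
            continue
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        rows.append(dos)
        mafs.append(maf)
        misses.append(miss)
        hwes.append(hwe)
    if n_multi:
        warnings.warn(f"skipped {n_multi} multi-allelic records", stacklevel=2)
    if not ids:
        warnings.warn("all SNPs filtered out", stacklevel=2)
        return GenotypeSet(
            snp_ids=[],
            chrom=np.array([], dtype=object),
            pos=np.array([], dtype=np.int64),
            dosage=np.zeros((len(samples), 0)),
            samples=samples,
            maf=np.array([]),
            missingness=np.array([]),
            hwe_p=np.array([]),
        )
    return GenotypeSet(
        snp_ids=ids,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        dosage=np.column_stack(rows) if rows else np.zeros((len(samples), 0)),
        samples=samples,
        maf=np.array(mafs),
        missingness=np.array(misses),
        hwe_p=np.array(hwes),
    )
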