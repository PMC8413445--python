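"""Genetic differentially methylated regions (gDMRs).

Per-SNP association t-statistics at adjacent cytosines are clustered by
genomic gap; maximal sign-homogeneous runs of sites with |t| above a cutoff
(default 5, liberal alternative 3.5) of at least two sites become regions.
Regions are labeled cis/trans against GWAS LD blocks, overlapped across
datasets, and scored for replication by the mean member p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "GDMR",
    "cluster_sites",
    "find_gdmrs",
    "classify_region",
    "overlap_regions",
    "region_replication",
    "gdmrs_to_frame",
    "gdmrs_to_bed",
]


@dataclass
class GDMR:
    chrom: str
    start: int  # 1-based inclusive, from member sites
    end: int
    snp: str
    n_sites: int
    mean_t: float
    mean_p: float
    sign: str  # "+" or "-"
    cis_flag: str | None = None
    member_idx: tuple[int, ...] = ()


def cluster_sites(positions: np.ndarray, maxgap: int = 1000) -> np.ndarray:
    """Cluster ids (1-based, increasing along the genome) for sorted
    positions; consecutive sites with gap <= maxgap share a cluster."""
    positions = np.asarray(positions, dtype=np.int64)
    if positions.size == 0:
        return np.array([], dtype=np.int64)
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    breaks = np.diff(positions) > maxgap
    return np.concatenate([[1], 1 + np.cumsum(breaks)]).astype(np.int64)


def find_gdmrs(
    t: np.ndarray,
    positions: np.ndarray,
    pvals: np.ndarray | None = None,
    snp: str = "",
    chrom: str = "chr1",
    cutoff: float = 5.0,
    maxgap: int = 1000,
    min_sites: int = 2,
) -> list[GDMR]:
    """Maximal runs of consecutive sites with |t| >= cutoff, sign-homogeneous,
    within a gap cluster, of at least ``min_sites`` sites."""
    t = np.asarray(t, dtype=float)
    positions = np.asarray(positions, dtype=np.int64)
    if pvals is None:
        pvals = np.full(t.shape, np.nan)
    pvals = np.asarray(pvals, dtype=float)
    clusters = cluster_sites(positions, maxgap=maxgap)
    out: list[GDMR] = []
    i, n = 0, t.size
    while i < n:
        if abs(t[i]) < cutoff:
            i += 1
            continue
        sign = np.sign(t[i])
        j = i
        while (
            j + 1 < n
            and clusters[j + 1] == clusters[i]
            and abs(t[j + 1]) >= cutoff
            and np.sign(t[j + 1]) == sign
        ):
            j += 1
        if j - i + 1 >= min_sites:
            member = np.arange(i, j + 1)
            member_p = pvals[member]
            mean_p = float(np.nanmean(member_p)) if np.any(~np.isnan(member_p)) else float("nan")
            out.append(
                GDMR(
                    chrom=chrom,
                    start=int(positions[i]),
                    end=int(positions[j]),
                    snp=snp,
                    n_sites=int(member.size),
                    mean_t=float(t[member].mean()),
                    mean_p=mean_p,
                    sign="+" if sign > 0 else "-",
                    member_idx=tuple(int(k) for k in member),
                )
            )
        i = j + 1
    return out


def classify_region(gdmr: GDMR, block: tuple[str, int, int] | None) -> str:
    """cis iff the region overlaps the (1-based inclusive) LD-block interval
    of its index SNP by any bp; else trans."""
    if block is None:
        raise ValueError(f"no LD block provided for SNP {gdmr.snp}")
    chrom, start, end = block
    if gdmr.chrom != chrom:
        return "trans"
    return "cis" if gdmr.start <= end and gdmr.end >= start else "trans"


def overlap_regions(a: list[GDMR], b: list[GDMR]):
    """Any-bp-overlap pairs (1-based inclusive coordinates) via sweep line.

    Returns (list of (i, j) index pairs, count of a-regions with >= 1
    overlap)."""
    pairs: list[tuple[int, int]] = []
    b_by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for j, r in enumerate(b):
        b_by_chrom.setdefault(r.chrom, []).append((r.start, r.end, j))
    for lst in b_by_chrom.values():
        lst.sort()
    for i, r in enumerate(a):
        for start, end, j in b_by_chrom.get(r.chrom, []):
            if start > r.end:
                break
            if end >= r.start:
                pairs.append((i, j))
    n_a_hit = len({i for i, _ in pairs})
    return pairs, n_a_hit


def region_replication(gdmr: GDMR, replication_p: dict[int, float], alpha: float = 0.05):
    """Mean member p-value in a replication dataset and a replicated flag
    (mean p < alpha). Member sites missing from the replication set are
    dropped; if none remain the flag is None (NA)."""
    ps = [replication_p[k] for k in gdmr.member_idx if k in replication_p]
    n_missing = gdmr.n_sites - len(ps)
    if not ps:
        return float("nan"), None, n_missing
    mean_p = float(np.mean(ps))
    return mean_p, bool(mean_p < alpha), n_missing


def gdmrs_to_frame(regions: list[GDMR]) -> pd.DataFrame:
    rows = [asdict(r) for r in regions]
    for r in rows:
        r.pop("member_idx")
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "snp", "n_sites", "mean_t", "mean_p", "sign", "cis_flag"],
    )


def gdmrs_to_bed(regions: list[GDMR], path: str) -> None:
    """BED (0-based half-open) with name=snp, score=mean |t|, strand=sign."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.snp}\t{abs(r.mean_t):.4f}\t{r.sign}\n"
            )
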