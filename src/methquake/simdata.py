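"""Synthetic genotypes, methylomes, covariates, expression and GWAS summaries.

The generator emulates the statistical structure a brain WGBS meQTL study
sees: bimodal CpG methylation (most sites highly methylated), mean read
coverage around 17x, additive SNP effects on windows of nearby CpGs (mean
per-allele shift 2.6% over ~14.5 kb), sparse large CpH effects, and
batch / neuronal-fraction / age covariate structure. Every injected effect
is recorded in a :class:`TruthTable` so downstream estimators can be scored
against ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .methio import GenotypeSet, MethylomeMatrix

__all__ = [
    "SimConfig",
    "TruthTable",
    "simulate_genotypes",
    "simulate_methylome",
    "sample_read_counts",
    "simulate_covariates",
    "simulate_expression_and_gwas",
    "simulate_dataset",
    "write_vcf",
]


@dataclass
class SimConfig:
    """All knobs of the generator, with defaults matching the study conditions.

    The defaults encode the observed data properties the pipeline is meant
    to handle: 78%/14%/8% high/intermediate/low baseline methylation mix,
    mean coverage 17.3 reads, mean per-allele CpG effect 0.026 (CpH 0.27),
    mean effect-window width 14.5 kb, and 94% of age-associated sites
    gaining methylation with age.
    """

    n_samples: int = 165
    n_snps: int = 500
    n_cpg: int = 5000
    n_cph: int = 0
    chrom_length: int = 250_000  # ~1 CpG per 50 bp: CpG-dense regulatory DNA
    chrom: str = "chr1"
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.8
    mean_coverage: float = 17.3
    baseline_mixture: tuple[float, float, float] = (0.78, 0.14, 0.08)
    meqtl_fraction: float = 0.3
    effect_mean_cpg: float = 0.026
    effect_mean_cph: float = 0.27
    effect_width_mean: float = 14_500.0
    age_site_fraction: float = 0.1
    age_increase_fraction: float = 0.94
    age_slope_sd: float = 0.0005  # per year of age
    age_region_width: int = 3000  # age effects come in coherent blocks
    batch_var_share: float = 0.10
    neuronal_slope_sd: float = 0.02
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if abs(sum(self.baseline_mixture) - 1.0) > 1e-9:
            raise ValueError("baseline_mixture must sum to 1")
        for name in ("meqtl_fraction", "age_site_fraction", "age_increase_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.chrom_length <= 40_000:
            raise ValueError("chrom_length must exceed downstream window sizes")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, salt]))


@dataclass
class TruthTable:
    """Ground truth of every injected effect.

    snp_effects: per SNP — effect size (0 when none), window (start, end)
    in bp, and the indices of affected sites.
    site_truth: per site — baseline methylation, age slope, batch offset,
    neuronal-fraction slope.
    mediation: per designated (snp, site, gene) triplet — the true mediated
    proportion of the genotype effect on expression.
    clipped: boolean mask of (site, sample) cells clipped to [0, 1].
    """

    snp_effect: np.ndarray
    snp_effect_cph: np.ndarray | None
    snp_window: np.ndarray  # (n_snps, 2) bp, -1 where no effect
    affected_sites: list[np.ndarray]
    baseline: np.ndarray
    age_slope: np.ndarray
    batch_offset: np.ndarray
    neuron_slope: np.ndarray
    clipped: np.ndarray | None = None
    mediation: pd.DataFrame | None = None
    gwas_tau: dict | None = None

    def true_pairs(self) -> list[tuple[int, int, float]]:
        """(snp index, site index, effect) for every injected association."""
        out = []
        for j, sites in enumerate(self.affected_sites):
            for s in sites:
                out.append((j, int(s), float(self.snp_effect[j])))
        return out


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(config: SimConfig) -> GenotypeSet:
    """Simulate biallelic dosages under Hardy-Weinberg with block LD.

    Haplotypes are generated from a latent AR(1) Gaussian copula within LD
    blocks (correlation ``ld_rho`` between adjacent SNPs), so marginal
    allele frequencies are exact and adjacent-SNP r2 is tunable; the two
    haplotypes of a sample are independent, hence HWE holds per SNP.
    """
    if config.n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if config.n_samples < 2:
        raise ValueError("degenerate config: n_samples < 2")
    rng = config.rng(salt=1)
    m = config.n_snps
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    pos = np.sort(rng.choice(np.arange(1, config.chrom_length + 1), size=m, replace=False))
    thresh = stats.norm.ppf(mafs)  # allele = minor with prob maf

    def haplotypes() -> np.ndarray:
        z = np.empty((config.n_samples, m))
        for start in range(0, m, config.ld_block_size):
            end = min(start + config.ld_block_size, m)
            block = rng.standard_normal((config.n_samples, end - start))
            for k in range(1, end - start):
                block[:, k] = config.ld_rho * block[:, k - 1] + np.sqrt(
                    1 - config.ld_rho**2
                ) * block[:, k]
            z[:, start:end] = block
        return (z < thresh).astype(np.int8)

    dosage = (haplotypes() + haplotypes()).astype(float)
    return GenotypeSet(
        snp_ids=[f"snp{i}" for i in range(m)],
        chrom=np.array([config.chrom] * m, dtype=object),
        pos=pos,
        dosage=dosage,
        samples=[f"S{i:04d}" for i in range(config.n_samples)],
    )


# ---------------------------------------------------------------------------
# covariates


def simulate_covariates(config: SimConfig) -> pd.DataFrame:
    """Age, sex, diagnosis, batch and neuronal fraction per sample."""
    rng = config.rng(salt=2)
    n = config.n_samples
    return pd.DataFrame(
        {
            "sample": [f"S{i:04d}" for i in range(n)],
            "age": rng.uniform(18, 96, size=n),
            "sex": rng.choice(["M", "F"], size=n),
            "diagnosis": rng.choice(["control", "case"], size=n),
            "batch": rng.integers(0, 2, size=n),
            "neuronal_fraction": rng.beta(8, 12, size=n),
        }
    ).set_index("sample")


# ---------------------------------------------------------------------------
# methylome


def _baseline_fractions(rng: np.random.Generator, n: int, weights) -> np.ndarray:
    """Three-component mixture: high (>0.8), intermediate, low (<0.2)."""
    cls = rng.choice(3, size=n, p=list(weights))
    base = np.empty(n)
    hi, mid, lo = cls == 0, cls == 1, cls == 2
    # within-class shapes are skewed away from the hard 0/1 boundaries:
    # highly methylated sites average ~85-90%, not full saturation, which
    # also keeps additive allelic shifts from being clipped wholesale
    base[hi] = 0.8 + 0.2 * rng.beta(1.5, 4, size=hi.sum())
    base[mid] = 0.2 + 0.6 * rng.beta(2, 2, size=mid.sum())
    base[lo] = 0.2 * (1 - rng.beta(1.5, 4, size=lo.sum()))
    return base


def simulate_methylome(
    genotypes: GenotypeSet, config: SimConfig
) -> tuple[np.ndarray, pd.DataFrame, TruthTable]:
    """True methylation fractions (sites x samples), site table, truth.

    CpG baselines follow the configured high/intermediate/low mixture; each
    effect-carrying SNP shifts methylation additively by dosage x effect at
    every CpG inside a window drawn around ``effect_width_mean``; CpH
    baselines are low (Beta(1.5, 30)) with sparse large effects. Batch,
    neuronal-fraction and age terms are added, then values are clipped to
    [0, 1] with the clip mask recorded.
    """
    if genotypes.dosage.shape[0] != config.n_samples:
        raise ValueError("genotype samples do not match config.n_samples")
    rng = config.rng(salt=3)
    covs = simulate_covariates(config)

    n_sites = config.n_cpg + config.n_cph
    pos = np.sort(rng.choice(np.arange(1, config.chrom_length + 1), size=n_sites, replace=False))
    context = np.array(["CpG"] * config.n_cpg + ["CpH"] * config.n_cph)
    rng.shuffle(context)
    sites = pd.DataFrame(
        {"chrom": config.chrom, "pos": pos, "context": context, "strand": "unknown"}
    )
    is_cpg = context == "CpG"

    baseline = np.empty(n_sites)
    baseline[is_cpg] = _baseline_fractions(rng, int(is_cpg.sum()), config.baseline_mixture)
    baseline[~is_cpg] = rng.beta(1.5, 30, size=int((~is_cpg).sum()))

    # SNP effects on windows of nearby sites
    m = genotypes.n_snps
    effect = np.zeros(m)
    window = np.full((m, 2), -1, dtype=np.int64)
    affected: list[np.ndarray] = [np.empty(0, dtype=np.int64) for _ in range(m)]
    is_meqtl = rng.random(m) < config.meqtl_fraction
    signs = rng.choice([-1.0, 1.0], size=m)
    mag_cpg = rng.gamma(2.0, config.effect_mean_cpg / 2.0, size=m)
    mag_cph = rng.gamma(4.0, config.effect_mean_cph / 4.0, size=m)
    widths = rng.gamma(2.0, config.effect_width_mean / 2.0, size=m)

    signal = np.zeros((n_sites, config.n_samples))
    dos = genotypes.dosage
    for j in range(m):
        if not is_meqtl[j]:
            continue
        center = genotypes.pos[j]
        half = widths[j] / 2.0
        lo, hi = center - half, center + half
        if lo < 1 or hi > config.chrom_length:
            warnings.warn("effect window truncated at chromosome end", stacklevel=2)
            lo, hi = max(lo, 1), min(hi, config.chrom_length)
        idx = np.flatnonzero((pos >= lo) & (pos <= hi))
        idx_cpg = idx[is_cpg[idx]]
        idx_cph = idx[~is_cpg[idx]]
        eff = signs[j] * mag_cpg[j]
        if idx_cpg.size == 0 and idx_cph.size == 0:
            continue
        window[j] = (int(lo), int(hi))
        if idx_cpg.size:
            signal[idx_cpg] += eff * dos[:, j][None, :]
        if idx_cph.size:
            signal[idx_cph] += signs[j] * mag_cph[j] * dos[:, j][None, :]
        effect[j] = eff
        affected[j] = np.concatenate([idx_cpg, idx_cph])

    # covariate structure; age effects are region-coherent (aging-associated
    # methylation drift spans kilobase blocks, not isolated cytosines),
    # which also survives local smoothing the way real age DMRs do
    age_slope = np.zeros(n_sites)
    n_age_target = int(round(config.age_site_fraction * n_sites))
    sites_per_region = max(1, int(round(n_sites * config.age_region_width / config.chrom_length)))
    n_regions = max(1, int(round(n_age_target / sites_per_region)))
    centers = rng.choice(config.chrom_length, size=n_regions, replace=False)
    half_w = config.age_region_width / 2.0
    region_slopes = np.abs(rng.normal(0, config.age_slope_sd, size=n_regions))
    neg = rng.random(n_regions) >= config.age_increase_fraction
    region_slopes[neg] *= -1
    for c, sl in zip(centers, region_slopes):
        idx = np.flatnonzero((pos >= c - half_w) & (pos <= c + half_w))
        age_slope[idx] = sl

    batch_sd = np.sqrt(config.batch_var_share) * 0.05
    batch_offset = rng.normal(0, batch_sd, size=n_sites)
    neuron_slope = rng.normal(0, config.neuronal_slope_sd, size=n_sites)

    age_c = covs["age"].to_numpy() - covs["age"].mean()
    batch = covs["batch"].to_numpy().astype(float)
    neuro_c = covs["neuronal_fraction"].to_numpy() - covs["neuronal_fraction"].mean()

    truth_frac = (
        baseline[:, None]
        + signal
        + age_slope[:, None] * age_c[None, :]
        + batch_offset[:, None] * batch[None, :]
        + neuron_slope[:, None] * neuro_c[None, :]
        + rng.normal(0, config.noise_sd, size=(n_sites, config.n_samples))
    )
    clipped = (truth_frac < 0) | (truth_frac > 1)
    truth_frac = np.clip(truth_frac, 0.0, 1.0)

    effect_cph = np.where(effect != 0, signs * mag_cph, 0.0)
    truth = TruthTable(
        snp_effect=effect,
        snp_effect_cph=effect_cph,
        snp_window=window,
        affected_sites=affected,
        baseline=baseline,
        age_slope=age_slope,
        batch_offset=batch_offset,
        neuron_slope=neuron_slope,
        clipped=clipped,
    )
    return truth_frac, sites, truth


# ---------------------------------------------------------------------------
# read counts


def _ztp_rate(mean: float) -> float:
    """Rate of a zero-truncated Poisson with the given mean."""
    if mean <= 1:
        raise ValueError("zero-truncated Poisson mean must exceed 1")
    f = lambda lam: lam / (1 - np.exp(-lam)) - mean
    return float(optimize.brentq(f, 1e-8, mean + 10))


def sample_read_counts(
    true_fractions: np.ndarray, sites: pd.DataFrame, config: SimConfig
) -> MethylomeMatrix:
    """Draw coverage (zero-truncated Poisson, mean ``mean_coverage``) and
    binomial methylated counts at the true fractions."""
    frac = np.asarray(true_fractions, dtype=float)
    if np.any(frac < 0) or np.any(frac > 1):
        raise ValueError("fractions must lie in [0, 1]")
    rng = config.rng(salt=4)
    lam = _ztp_rate(config.mean_coverage)
    u = rng.uniform(np.exp(-lam), 1.0, size=frac.shape)
    coverage = stats.poisson.ppf(u, lam).astype(np.int64)
    methylated = rng.binomial(coverage, frac)
    return MethylomeMatrix(
        sites=sites,
        samples=[f"S{i:04d}" for i in range(config.n_samples)],
        methylated=methylated,
        coverage=coverage,
    )


# ---------------------------------------------------------------------------
# expression + GWAS


def simulate_expression_and_gwas(
    genotypes: GenotypeSet,
    truth: TruthTable,
    config: SimConfig,
    true_fractions: np.ndarray | None = None,
    n_genes: int = 20,
    mediation_props: tuple[float, ...] = (0.0, 0.3, 0.6, 0.9),
    gwas_n: int = 50_000,
    gwas_tau: dict[str, float] | None = None,
    annotations: dict[str, np.ndarray] | None = None,
    ld_scores: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression with controlled mediation, and GWAS z-scores under the
    stratified heritability model.

    Mediated genes: expression = direct*dosage + indirect路methylation + noise,
    with the true mediated proportion (indirect share of the total genotype
    effect) cycling through ``mediation_props``. GWAS: per-SNP
    chi-square expectation 1 + N * sum_c tau_c * l_jc.
    """
    rng = config.rng(salt=5)
    effect_snps = np.flatnonzero(truth.snp_effect != 0)
    if mediation_props and effect_snps.size == 0:
        raise ValueError("cannot build mediation triplets: no meQTL effects simulated")
    # triplets are designated at loci with clear allelic signal, mirroring
    # the double-significance (eQTL and meQTL) precondition of the analysis:
    # a near-zero marginal coefficient makes the retained proportion a
    # ratio of noise
    strong = effect_snps[np.abs(truth.snp_effect[effect_snps]) >= 0.02]
    if strong.size > 0:
        effect_snps = strong

    rows = []
    expr = {}
    levels = ["gene", "exon", "junction"]
    for g in range(n_genes):
        snp = int(rng.choice(effect_snps))
        site_choices = truth.affected_sites[snp]
        # designate a site whose allelic signal survived [0,1] clipping: a
        # saturated site carries no meQTL signal and could never pass the
        # expression-methylation correlation gate downstream
        if truth.clipped is not None:
            clip_frac = truth.clipped[site_choices].mean(axis=1)
            ok = site_choices[clip_frac < 0.05]
            if ok.size == 0:
                ok = site_choices[clip_frac <= clip_frac.min()]
            site_choices = ok
        site = int(rng.choice(site_choices))
        prop = mediation_props[g % len(mediation_props)]
        if true_fractions is not None:
            meth = true_fractions[site]
        else:
            meth = truth.baseline[site] + truth.snp_effect[snp] * genotypes.dosage[:, snp]
        dos = genotypes.dosage[:, snp]
        alpha = truth.snp_effect[snp]  # dosage -> methylation slope
        delta = 5.0  # methylation -> expression slope
        total = delta * alpha / max(prop, 1e-12) if prop > 0 else delta * alpha
        if prop > 0:
            direct = total * (1 - prop)
        else:
            # no mediated path contributes: expression depends on dosage only
            direct, delta = 1.0, 0.0
        noise = rng.normal(0, 0.05, size=config.n_samples)
        feature = f"feat{g}"
        expr[feature] = direct * dos + delta * meth + noise
        rows.append(
            {
                "feature": feature,
                "level": levels[g % 3],
                "snp": snp,
                "site": site,
                "true_mediation": prop,
            }
        )
    truth.mediation = pd.DataFrame(rows)
    expr_df = pd.DataFrame(expr, index=[f"S{i:04d}" for i in range(config.n_samples)]).T
    expr_df.insert(0, "level", [r["level"] for r in rows])

    # GWAS summary statistics under the stratified model
    m = genotypes.n_snps
    if gwas_tau is None:
        gwas_tau = {}
    if ld_scores is None:
        ld_total = np.ones(m)
        var = np.ones(m)
        for name, tau in gwas_tau.items():
            member = annotations[name].astype(float)
            var = var + gwas_n * tau * member  # l_jc ~ membership when no LD given
    else:
        var = np.ones(m)
        for name, tau in gwas_tau.items():
            var = var + gwas_n * tau * ld_scores[:, list(annotations).index(name)]
    z = rng.normal(0, 1, size=m) * np.sqrt(var)
    gwas = pd.DataFrame(
        {
            "SNP": genotypes.snp_ids,
            "chrom": genotypes.chrom,
            "pos": genotypes.pos,
            "N": gwas_n,
            "Z": z,
        }
    )
    truth.gwas_tau = dict(gwas_tau)
    return expr_df, gwas


# ---------------------------------------------------------------------------
# writers


def write_vcf(genotypes: GenotypeSet, path: str) -> None:
    """Write dosages as a minimal VCF v4.2 with GT fields (unphased)."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = pd.unique(genotypes.chrom)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples)
            + "\n"
        )
        for j in range(genotypes.n_snps):
            gts = [
                gt_map.get(genotypes.dosage[i, j], "./.")
                for i in range(len(genotypes.samples))
            ]
            fh.write(
                f"{genotypes.chrom[j]}\t{genotypes.pos[j]}\t{genotypes.snp_ids[j]}"
                f"\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def simulate_replication(
    genotypes: GenotypeSet,
    sites: pd.DataFrame,
    truth: TruthTable,
    config: SimConfig,
    keep_snps: np.ndarray,
    seed: int,
) -> tuple[np.ndarray, MethylomeMatrix]:
    """A second dataset sharing a known subset of the genetic effects.

    Rebuilds true fractions from the recorded truth with only the effects of
    ``keep_snps`` (boolean mask over SNPs) retained, fresh noise, and fresh
    read counts; covariate terms are re-drawn. Used to create replication
    cohorts whose shared-effect fraction is known exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 6]))
    n_sites = len(sites)
    pos = sites["pos"].to_numpy()
    signal = np.zeros((n_sites, config.n_samples))
    is_cpg = (sites["context"] == "CpG").to_numpy()
    for j in np.flatnonzero(keep_snps):
        if truth.snp_effect[j] == 0:
            continue
        for s in truth.affected_sites[j]:
            eff = truth.snp_effect[j] if is_cpg[s] else truth.snp_effect_cph[j]
            signal[s] += eff * genotypes.dosage[:, j]
    frac = (
        truth.baseline[:, None]
        + signal
        + rng.normal(0, config.noise_sd, size=(n_sites, config.n_samples))
    )
    frac = np.clip(frac, 0.0, 1.0)
    lam = _ztp_rate(config.mean_coverage)
    u = rng.uniform(np.exp(-lam), 1.0, size=frac.shape)
    coverage = stats.poisson.ppf(u, lam).astype(np.int64)
    methylated = rng.binomial(coverage, frac)
    repl = MethylomeMatrix(
        sites=sites.copy(),
        samples=[f"S{i:04d}" for i in range(config.n_samples)],
        methylated=methylated,
        coverage=coverage,
    )
    return frac, repl


def simulate_dataset(config: SimConfig):
    """Convenience: genotypes, methylome (with counts), covariates, truth."""
    genotypes = simulate_genotypes(config)
    frac, sites, truth = simulate_methylome(genotypes, config)
    methylome = sample_read_counts(frac, sites, config)
    covariates = simulate_covariates(config)
    return genotypes, methylome, covariates, frac, truth
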