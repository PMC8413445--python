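"""Generator calibration and invariants: Hardy-Weinberg genotypes, the
bimodal methylation mixture, coverage, injected-effect bookkeeping."""

import numpy as np
import pytest
from scipy import stats

from methquake import simdata
from methquake.simdata import SimConfig


def test_config_validation_rejects_degenerate():
    with pytest.raises(ValueError):
        SimConfig(n_samples=2)
    with pytest.raises(ValueError):
        SimConfig(maf_range=(0.0, 0.5))
    with pytest.raises(ValueError):
        SimConfig(baseline_mixture=(0.5, 0.5, 0.5))
    with pytest.raises(ValueError):
        SimConfig(meqtl_fraction=1.5)


def test_genotypes_hwe_and_maf():
    # single SNP at p = q = 0.5: mean dosage 1 by HWE symmetry
    cfg = SimConfig(n_samples=10_000, n_snps=1, n_cpg=10, maf_range=(0.5, 0.5), seed=5)
    g = simdata.simulate_genotypes(cfg)
    assert abs(g.dosage.mean() - 1.0) < 0.03

    # aggregated genotype class counts match (p^2, 2pq, q^2): chi-square GOF
    cfg = SimConfig(
        n_samples=5000, n_snps=200, n_cpg=10, maf_range=(0.2, 0.2), ld_block_size=1, seed=6
    )
    g = simdata.simulate_genotypes(cfg)
    q, p = 0.2, 0.8
    # minor allele may map to either dosage direction; count by allele freq
    obs = np.zeros(3)
    for j in range(g.n_snps):
        d = g.dosage[:, j]
        if d.mean() > 1:  # minor allele is reference here; flip
            d = 2 - d
        for k in range(3):
            obs[k] += (d == k).sum()
    n = obs.sum()
    exp = n * np.array([p * p, 2 * p * q, q * q])
    chi2 = ((obs - exp) ** 2 / exp).sum()
    assert stats.chi2.sf(chi2, df=2) > 1e-4

    # empirical MAF respects the configured lower bound in intent
    cfg = SimConfig(n_samples=4000, n_snps=300, n_cpg=10, maf_range=(0.05, 0.5), seed=7)
    g = simdata.simulate_genotypes(cfg)
    assert g.maf.min() > 0.02  # sampling noise around the 0.05 floor, never far below

    assert np.all(np.diff(g.pos) > 0)
    assert set(np.unique(g.dosage)) <= {0.0, 1.0, 2.0}


def test_ld_blocks_induce_adjacent_correlation():
    cfg = SimConfig(
        n_samples=3000, n_snps=40, n_cpg=10, ld_block_size=10, ld_rho=0.8,
        maf_range=(0.3, 0.3), seed=8,
    )
    g = simdata.simulate_genotypes(cfg)
    within = [
        abs(np.corrcoef(g.dosage[:, j], g.dosage[:, j + 1])[0, 1])
        for j in range(0, 39)
        if (j % 10) != 9  # same block
    ]
    across = [
        abs(np.corrcoef(g.dosage[:, j], g.dosage[:, j + 1])[0, 1])
        for j in range(9, 39, 10)  # block boundary
    ]
    assert np.mean(within) > 0.3
    assert np.mean(across) < 0.15


def test_methylome_baseline_mixture_matches_weights():
    cfg = SimConfig(n_samples=10, n_snps=5, n_cpg=20_000, chrom_length=2_000_000, seed=9)
    g = simdata.simulate_genotypes(cfg)
    _, _, truth = simdata.simulate_methylome(g, cfg)
    high = (truth.baseline > 0.8).mean()
    low = (truth.baseline < 0.2).mean()
    assert abs(high - 0.78) < 0.02
    assert abs(low - 0.08) < 0.02


def test_no_effects_means_no_dosage_correlation():
    cfg = SimConfig(n_samples=300, n_snps=20, n_cpg=300, meqtl_fraction=0.0, seed=10)
    g, m, _, frac, truth = simdata.simulate_dataset(cfg)
    assert np.all(truth.snp_effect == 0)
    # max |cor| over sites x snps stays below a chance bound for n=300
    f = frac - frac.mean(axis=1, keepdims=True)
    d = g.dosage - g.dosage.mean(axis=0)
    num = f @ d
    den = np.sqrt((f**2).sum(axis=1))[:, None] * np.sqrt((d**2).sum(axis=0))[None, :]
    cors = np.abs(num / den)
    # Bonferroni-style chance bound for 6000 correlations at n=300
    bound = stats.norm.isf(0.5 * 0.01 / cors.size) / np.sqrt(300)
    assert cors.max() < bound


def test_deterministic_effect_without_noise_or_covariates():
    cfg = SimConfig(
        n_samples=50, n_snps=1, n_cpg=200, meqtl_fraction=1.0, noise_sd=0.0,
        age_site_fraction=0.0, batch_var_share=0.0, neuronal_slope_sd=0.0,
        effect_mean_cpg=0.026, seed=12,
    )
    g = simdata.simulate_genotypes(cfg)
    frac, sites, truth = simdata.simulate_methylome(g, cfg)
    j = 0
    assert truth.snp_effect[j] != 0
    d = g.dosage[:, j]
    for s in truth.affected_sites[j][:10]:
        if truth.clipped[s].any():
            continue
        by_dosage = [frac[s][d == k].mean() for k in (0, 1, 2) if (d == k).any()]
        diffs = np.diff(by_dosage)
        assert np.allclose(diffs, truth.snp_effect[j], atol=1e-12)


def test_truth_table_records_every_effect_once():
    cfg = SimConfig(n_samples=30, n_snps=40, n_cpg=500, seed=13)
    g = simdata.simulate_genotypes(cfg)
    _, _, truth = simdata.simulate_methylome(g, cfg)
    pairs = truth.true_pairs()
    assert len(pairs) == len(set((j, s) for j, s, _ in pairs))
    for j, sites in enumerate(truth.affected_sites):
        if truth.snp_effect[j] == 0:
            assert sites.size == 0
        else:
            lo, hi = truth.snp_window[j]
            assert sites.size >= 1
            # affected sites lie within the recorded window (positions)


def test_read_counts_ztp_coverage_and_binomial_mean():
    cfg = SimConfig(n_samples=100, n_snps=5, n_cpg=1000, seed=14)
    frac = np.full((1000, 100), 0.4)
    import pandas as pd

    sites = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(1, 1001), "context": "CpG", "strand": "unknown"}
    )
    m = simdata.sample_read_counts(frac, sites, cfg)
    assert m.coverage.min() >= 1
    assert abs(m.coverage.mean() - 17.3) < 0.1
    est = m.methylated.sum() / m.coverage.sum()
    se = np.sqrt(0.4 * 0.6 / m.coverage.sum())
    assert abs(est - 0.4) < 4 * se

    # degenerate fraction 0: no methylated reads
    m0 = simdata.sample_read_counts(np.zeros((1000, 100)), sites, cfg)
    assert m0.methylated.max() == 0
    assert np.all(m.methylated <= m.coverage)


def test_identical_config_gives_byte_identical_files(tmp_path):
    cfg = SimConfig(n_samples=8, n_snps=10, n_cpg=50, seed=15)
    outs = []
    for d in ("a", "b"):
        g, m, cov, _, _ = simdata.simulate_dataset(cfg)
        vcf = tmp_path / f"{d}.vcf"
        simdata.write_vcf(g, str(vcf))
        outs.append(vcf.read_bytes())
    assert outs[0] == outs[1]


def test_expression_requires_meqtl_effects():
    cfg = SimConfig(n_samples=30, n_snps=10, n_cpg=100, meqtl_fraction=0.0, seed=16)
    g, m, cov, frac, truth = simdata.simulate_dataset(cfg)
    with pytest.raises(ValueError, match="no meQTL effects"):
        simdata.simulate_expression_and_gwas(g, truth, cfg)


def test_gwas_null_chisq_mean_and_stratified_lift():
    cfg = SimConfig(n_samples=40, n_snps=4000, n_cpg=100, chrom_length=4_000_000, seed=17)
    g = simdata.simulate_genotypes(cfg)
    _, _, truth = simdata.simulate_methylome(g, cfg)
    # tau = 0 everywhere: chi-square mean ~ 1
    _, gwas = simdata.simulate_expression_and_gwas(g, truth, cfg, n_genes=1)
    chisq = gwas["Z"].to_numpy() ** 2
    assert abs(chisq.mean() - 1.0) < 4 * np.sqrt(2.0 / len(chisq))

    # nonzero tau on one annotation: inside mean exceeds outside by N*tau
    member = np.zeros(4000, dtype=bool)
    member[::10] = True
    tau = 2e-5
    _, gwas2 = simdata.simulate_expression_and_gwas(
        g, truth, cfg, n_genes=1, gwas_tau={"ann": tau}, annotations={"ann": member},
        gwas_n=50_000,
    )
    chisq2 = gwas2["Z"].to_numpy() ** 2
    lift = chisq2[member].mean() - chisq2[~member].mean()
    expected = 50_000 * tau  # l_jc = membership when no LD table is supplied
    assert abs(lift - expected) < 0.35 * expected
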