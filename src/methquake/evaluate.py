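"""Simulation studies scoring the pipeline against generative truth.

Each function simulates data under known conditions, runs the relevant
pipeline stage end to end, and reports how well the injected quantities are
recovered: per-allele slopes, cross-dataset pi1 sharing, mediation
proportions, REML heritability, stratified-regression coefficients, and
null calibration of the scan. These are the package's built-in validation
experiments; the acceptance script and the test suite both drive them.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import herit, mediation, meqtl, methio, sharing, simdata

__all__ = [
    "true_covariate_matrix",
    "scan_with_truth",
    "slope_recovery",
    "pi1_recovery",
    "mediation_recovery",
    "reml_recovery",
    "stratified_recovery",
    "null_calibration",
]


def true_covariate_matrix(covariates: pd.DataFrame) -> np.ndarray:
    """The generative confounders (age, batch, neuronal fraction) as a
    design block for adjustment in recovery experiments."""
    return np.column_stack(
        [
            covariates["age"].to_numpy(),
            covariates["batch"].to_numpy(dtype=float),
            covariates["neuronal_fraction"].to_numpy(),
        ]
    )


def scan_with_truth(config: simdata.SimConfig):
    """Simulate, preprocess and scan once; return everything downstream
    recovery analyses need."""
    genotypes, methylome, covariates, frac, truth = simdata.simulate_dataset(config)
    filtered = methio.filter_cpg(methylome)
    smoothed = methio.smooth_methylome(filtered)
    C = true_covariate_matrix(covariates)
    scanner = meqtl.MeQtlScanner(covariates=C).fit(genotypes, smoothed)
    # map original site indices to post-filter indices by position
    orig_pos = methylome.sites["pos"].to_numpy()
    filt_pos = smoothed.sites["pos"].to_numpy()
    pos_to_filtered = {int(p): i for i, p in enumerate(filt_pos)}
    return {
        "genotypes": genotypes,
        "methylome": methylome,
        "smoothed": smoothed,
        "covariates": covariates,
        "frac": frac,
        "truth": truth,
        "scanner": scanner,
        "orig_pos": orig_pos,
        "pos_to_filtered": pos_to_filtered,
    }


def slope_recovery(config: simdata.SimConfig | None = None, seed: int = 0) -> dict:
    """Mean estimated per-allele slope among injected (SNP, site) pairs
    compared with the injected mean, plus the scan-level summaries the
    study reports (meQTL SNP fraction, widths, sites per SNP)."""
    if config is None:
        config = simdata.SimConfig(seed=seed)
    run = scan_with_truth(config)
    truth, scanner = run["truth"], run["scanner"]
    pairs = run["scanner"].pairs_.set_index(["snp_idx", "site_idx"])
    est, tru = [], []
    for j, s, e in truth.true_pairs():
        fi = run["pos_to_filtered"].get(int(run["orig_pos"][s]))
        if fi is None:
            continue
        key = (j, fi)
        if key in pairs.index:
            est.append(float(pairs.loc[key, "slope"]))
            tru.append(e)
    est, tru = np.array(est), np.array(tru)
    mean_true = float(np.abs(tru).mean())
    mean_est = float(np.mean(est * np.sign(tru)))
    sig = scanner.significant_
    summary = meqtl.summarize_snp(sig)
    n_meqtl_snps = sig["snp"].nunique()
    return {
        "mean_true_effect": mean_true,
        "mean_est_slope": mean_est,
        "ratio": mean_est / mean_true,
        "n_true_pairs": int(est.size),
        "n_tests": scanner.n_tests_,
        "fdr_cutoff": scanner.fdr_cutoff_,
        "n_significant_pairs": int(len(sig)),
        "frac_snps_meqtl": float(n_meqtl_snps / run["genotypes"].n_snps),
        "mean_sig_sites_per_snp": float(summary["n_sites"].mean()) if len(summary) else 0.0,
        "mean_sig_width_bp": float(summary["width_bp"].mean()) if len(summary) else 0.0,
        "mean_abs_sig_slope": float(summary["mean_abs_slope"].mean()) if len(summary) else 0.0,
    }


def _block_of(config: simdata.SimConfig, j: int) -> int:
    return j // config.ld_block_size


def pi1_recovery(
    shared_fractions=(0.0, 0.5, 0.8, 1.0),
    config: simdata.SimConfig | None = None,
    seed: int = 0,
) -> list[dict]:
    """pi1 of replication statistics at discovery-significant pairs when a
    known fraction of effect SNPs keeps its effect in the replication set.

    The generative truth of each discovery-significant pair (j, s) is
    computed on the smoothed noiseless retained signal — the quantity the
    scan actually tests: the pair is non-null when the induced per-allele
    slope at s exceeds a small detectability floor. The default experiment
    uses unlinked SNPs and mostly disjoint effect windows so pairs owe
    their signal to one SNP each.
    """
    if config is None:
        # many unlinked effect SNPs with mostly disjoint windows: pi1's
        # effective sample size is the number of independent effect loci,
        # not the raw pair count (pairs of one SNP are strongly correlated)
        config = simdata.SimConfig(
            n_samples=165,
            n_snps=120,
            n_cpg=36_000,
            chrom_length=1_800_000,
            ld_block_size=1,
            meqtl_fraction=0.5,
            seed=seed,
        )
    run = scan_with_truth(config)
    genotypes, truth, scanner = run["genotypes"], run["truth"], run["scanner"]
    sig = scanner.significant_[["snp_idx", "site_idx"]].drop_duplicates()
    if len(sig) == 0:
        raise RuntimeError("discovery scan found no significant pairs")
    filt_pos = run["smoothed"].sites["pos"].to_numpy()
    orig_by_pos = {int(p): i for i, p in enumerate(run["orig_pos"])}
    filt_orig = np.array([orig_by_pos[int(p)] for p in filt_pos])
    effect_snps = np.flatnonzero(truth.snp_effect != 0)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    C = true_covariate_matrix(run["covariates"])
    plan = methio._WindowPlan(filt_pos, min_sites=70, min_width=2000)
    ones = np.ones(filt_pos.size)

    sig_snp = sig["snp_idx"].to_numpy()
    sig_site = sig["site_idx"].to_numpy()
    dos = genotypes.dosage
    dos_c = dos - dos.mean(axis=0)
    dos_var = dos_c.var(axis=0)

    out = []
    for f in shared_fractions:
        keep = np.zeros(genotypes.n_snps, dtype=bool)
        k = int(round(f * effect_snps.size))
        keep[rng.choice(effect_snps, size=k, replace=False)] = True
        _, repl = simdata.simulate_replication(
            genotypes, run["methylome"].sites, truth, config, keep, seed=seed + 1000 + int(f * 100)
        )
        repl_sm = methio.smooth_methylome(methio.filter_cpg(repl))
        repl_scan = meqtl.MeQtlScanner(covariates=C).fit(genotypes, repl_sm)
        est = sharing.pi1_sharing(
            scanner.significant_, repl_scan.pairs_, keys=("snp_idx", "site_idx")
        )
        # truth: smoothed noiseless retained signal at the filtered sites,
        # then the per-allele slope it induces for the pair's SNP
        signal = np.zeros((filt_pos.size, config.n_samples))
        for k_snp in np.flatnonzero(keep):
            eff = truth.snp_effect[k_snp]
            hit = np.isin(filt_orig, truth.affected_sites[k_snp])
            if hit.any():
                signal[hit] += eff * dos[:, k_snp][None, :]
        sm_signal = np.empty_like(signal)
        for i in range(config.n_samples):
            sm_signal[:, i] = methio._plan_smooth(plan, signal[:, i], ones, clip=False)
        induced = np.array(
            [
                abs(float(sm_signal[s] @ dos_c[:, j]) / (config.n_samples * dos_var[j]))
                for j, s in zip(sig_snp, sig_site)
            ]
        )
        nonnull = induced > 0.002  # below ~1 SE at this n: effectively null
        out.append(
            {
                "shared_fraction": float(f),
                "pi1": est.pi1,
                "truth": float(np.mean(nonnull)),
                "n_pairs": est.n_pvalues,
            }
        )
    return out


def mediation_recovery(
    truths=(0.0, 0.3, 0.6, 0.9),
    n_reps: int = 200,
    config: simdata.SimConfig | None = None,
    seed: int = 0,
) -> dict[float, float]:
    """Mean estimated mediated proportion (1 - prop_retained) per true
    mediation level, over replicate expression draws at randomly chosen
    effect loci. Unlinked SNPs keep the designated CpG's dosage slope equal
    to the injected effect; records the fit itself flags unstable (near-zero
    marginal coefficient) are excluded, as in the analysis proper."""
    if config is None:
        config = simdata.SimConfig(ld_block_size=1, seed=seed)
    genotypes, _, covariates, frac, truth = simdata.simulate_dataset(config)
    acc: dict[float, list[float]] = {float(t): [] for t in truths}
    for rep in range(n_reps):
        cfg_rep = replace(config, seed=seed + 50_000 + rep)
        expr, _ = simdata.simulate_expression_and_gwas(
            genotypes, truth, cfg_rep, true_fractions=frac,
            n_genes=len(truths), mediation_props=tuple(truths),
        )
        values = expr.drop(columns="level").to_numpy(dtype=float)
        for (_, row), e in zip(truth.mediation.iterrows(), values):
            rec = mediation.mediation_fit(
                e, genotypes.dosage[:, int(row["snp"])], frac[int(row["site"])]
            )
            if np.isfinite(rec.prop_retained) and not rec.unstable:
                acc[float(row["true_mediation"])].append(1.0 - rec.prop_retained)
    return {t: float(np.mean(v)) for t, v in acc.items()}


def reml_recovery(
    h2: float = 0.5,
    n_samples: int = 160,
    n_snps: int = 500,
    n_reps: int = 200,
    seed: int = 0,
) -> dict:
    """Mean REML heritability estimate when traits are simulated from the
    GRM with known h2."""
    cfg = simdata.SimConfig(
        n_samples=n_samples, n_snps=n_snps, n_cpg=10,
        chrom_length=max(50_001, 40 * n_snps), ld_block_size=1, seed=seed,
    )
    genotypes = simdata.simulate_genotypes(cfg)
    X = genotypes.dosage
    p = X.mean(axis=0) / 2
    keep = (p > 0) & (p < 1)
    Z = (X[:, keep] - 2 * p[keep]) / np.sqrt(2 * p[keep] * (1 - p[keep]))
    grm = herit.compute_grm(X)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
    ests = []
    m = int(keep.sum())
    for _ in range(n_reps):
        u = rng.normal(0, np.sqrt(h2 / m), size=m)
        C = rng.standard_normal((n_samples, 2))
        y = Z @ u + C @ rng.normal(0, 0.5, 2) + rng.normal(0, np.sqrt(1 - h2), n_samples)
        ests.append(herit.reml_h2(y, grm, C).h2)
    ests = np.array(ests)
    return {"h2_true": h2, "h2_mean": float(ests.mean()), "h2_sd": float(ests.std()), "n_reps": n_reps}


def stratified_recovery(
    n_snps: int = 20_000,
    n_samples: int = 200,
    n_gwas: float = 50_000,
    tau_base: float = 1e-5,
    tau_dmr: float = 5e-5,
    dmr_fraction: float = 0.05,
    window: int = 5_000,
    n_reps: int = 100,
    n_blocks: int = 20,
    seed: int = 0,
) -> dict:
    """Coverage of jackknife CIs for tau and enrichment over replicate GWAS
    draws from the stratified model, on one fixed genotype panel."""
    cfg = simdata.SimConfig(
        n_samples=n_samples, n_snps=n_snps, n_cpg=10,
        chrom_length=200 * n_snps, ld_block_size=10, ld_rho=0.9, seed=seed,
    )
    genotypes = simdata.simulate_genotypes(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 55]))
    member = np.zeros(n_snps, dtype=bool)
    member[rng.choice(n_snps, size=int(dmr_fraction * n_snps), replace=False)] = True
    ann = {"all": np.ones(n_snps, dtype=bool), "dmr": member}
    tbl = herit.ld_scores(genotypes.dosage, genotypes.pos, ann, window=window)
    L = tbl.to_numpy()
    var = 1.0 + n_gwas * (tau_base * L[:, 0] + tau_dmr * L[:, 1])

    per_snp_true = tau_base + tau_dmr * member
    share_true = per_snp_true[member].sum() / per_snp_true.sum()
    enrich_true = share_true / member.mean()

    tau_cover = enrich_cover = 0
    last = None
    for _ in range(n_reps):
        z = rng.normal(0, 1, size=n_snps) * np.sqrt(var)
        res = herit.stratified_regression(z**2, tbl, n_gwas, ann, n_blocks=n_blocks)
        i = res.annotations.index("dmr")
        if abs(res.tau[i] - tau_dmr) <= 1.96 * res.tau_se[i]:
            tau_cover += 1
        if abs(res.enrichment[i] - enrich_true) <= 1.96 * res.enrichment_se[i]:
            enrich_cover += 1
        last = res
    return {
        "tau_coverage": tau_cover / n_reps,
        "enrichment_coverage": enrich_cover / n_reps,
        "enrichment_true": float(enrich_true),
        "enrichment_last": float(last.enrichment[last.annotations.index("dmr")]),
        "n_reps": n_reps,
    }


def null_calibration(
    n_samples: int = 200,
    n_snps: int = 500,
    n_cpg: int = 5000,
    seed: int = 0,
    interaction_snps: int = 60,
    interaction_window: int = 4000,
) -> dict:
    """Scan a methylome with no genetic effects: the BH cutoff should find
    (almost) nothing, and the genotype x age interaction test should reject
    at its nominal rate."""
    cfg = simdata.SimConfig(
        n_samples=n_samples, n_snps=n_snps, n_cpg=n_cpg, meqtl_fraction=0.0, seed=seed
    )
    genotypes, methylome, covariates, _, _ = simdata.simulate_dataset(cfg)
    smoothed = methio.smooth_methylome(methio.filter_cpg(methylome))
    C = true_covariate_matrix(covariates)
    scanner = meqtl.MeQtlScanner(covariates=C).fit(genotypes, smoothed)
    if scanner.fdr_cutoff_ is None:
        n_disc = 0
    else:
        n_disc = int((scanner.pairs_["p"] <= scanner.fdr_cutoff_).sum())
    fdp = 0.0 if n_disc == 0 else 1.0  # every discovery on a null methylome is false

    # interaction type-I error on raw fractions (per-site binomial noise)
    raw = methio.filter_cpg(methylome)
    sub = genotypes.take_snps(np.arange(min(interaction_snps, genotypes.n_snps)))
    inter = meqtl.interaction_scan(
        sub, raw, covariates["age"].to_numpy(), window=interaction_window
    )
    type1 = float((inter["p"] < 0.05).mean())
    return {
        "n_tests": scanner.n_tests_,
        "n_discoveries": n_disc,
        "fdp": fdp,
        "interaction_type1": type1,
        "n_interaction_pairs": int(len(inter)),
    }
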