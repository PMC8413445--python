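"""End-to-end orchestration from a single config with reproducible artifacts."""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import diffmeth, gdmr, herit, mediation, meqtl, methio, sharing, simdata, varstruct

__all__ = ["RunConfig", "validate_config", "run_pipeline"]

_STAGES = ("simulate", "preprocess", "variance", "scan", "gdmr", "sharing", "mediation", "diffmeth", "herit")

_DEFAULTS = {
    "out_dir": None,  # required
    "seed": 0,
    "stages": list(_STAGES),
    # simulation
    "n_samples": 165,
    "n_snps": 500,
    "n_cpg": 5000,
    "n_cph": 0,
    "chrom_length": 5_000_000,
    "meqtl_fraction": 0.3,
    "mean_coverage": 17.3,
    # preprocess
    "min_cov_cpg": 3,
    "smooth_min_sites": 70,
    "smooth_min_width": 2000,
    # scan
    "window": 20_000,
    "cis_window": 250_000,
    "fdr": 0.01,
    "n_pcs": None,  # default min(28, n_samples // 6)
    "p_keep": 1.0,
    # gdmr
    "t_cutoff": 5.0,
    "t_cutoff_liberal": 3.5,
    "maxgap": 1000,
    "min_region_sites": 2,
    # mediation
    "cor_threshold": 0.3,
    "prop_threshold": 0.75,
    # heritability
    "relatedness_threshold": 0.025,
    "grm_window": 40_000,
    "ld_window": 1_000_000,
    "jackknife_blocks": 20,
}


@dataclass
class RunConfig:
    params: dict = field(default_factory=dict)

    def __getattr__(self, name):
        try:
            return self.params[name]
        except KeyError as exc:
            raise AttributeError(name) from exc


def validate_config(raw) -> RunConfig:
    """Type- and range-check a raw config mapping (or YAML path).

    Unknown keys are rejected; defaults (which mirror the study's printed
    parameter values) fill the gaps; the resolved config is returned and can
    be round-tripped through YAML bit-identically.
    """
    if isinstance(raw, (str, os.PathLike)):
        with open(raw) as fh:
            raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    params = {**_DEFAULTS, **raw}
    if params["out_dir"] is None:
        raise ValueError("missing required path: out_dir")
    for key in ("window", "cis_window", "maxgap", "grm_window", "ld_window", "chrom_length"):
        if params[key] is not None and params[key] <= 0:
            raise ValueError(f"{key} must be positive")
    for key in ("fdr", "cor_threshold", "prop_threshold", "meqtl_fraction"):
        if not (0 <= params[key] <= 1):
            raise ValueError(f"{key} must be in [0, 1]")
    bad = [s for s in params["stages"] if s not in _STAGES]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    return RunConfig(params=params)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute enabled stages in dependency order; returns the manifest.

    Every artifact is written under ``out_dir`` and checksummed; identical
    configs (including seed) produce byte-identical artifacts.
    """
    p = config.params
    out = p["out_dir"]
    os.makedirs(out, exist_ok=True)
    stages = list(p["stages"])
    manifest: dict = {"stages": stages, "outputs": {}, "counts": {}, "status": "incomplete"}

    def emit(name: str, path: str):
        manifest["outputs"][name] = {"path": os.path.relpath(path, out), "sha256": _sha256(path)}

    # out_dir is normalized in the echoed config so identical runs into
    # different directories remain byte-identical
    with open(os.path.join(out, "config.yaml"), "w") as fh:
        yaml.safe_dump({**p, "out_dir": "."}, fh, sort_keys=True)
    emit("config", os.path.join(out, "config.yaml"))

    sim = simdata.SimConfig(
        n_samples=p["n_samples"],
        n_snps=p["n_snps"],
        n_cpg=p["n_cpg"],
        n_cph=p["n_cph"],
        chrom_length=p["chrom_length"],
        meqtl_fraction=p["meqtl_fraction"],
        mean_coverage=p["mean_coverage"],
        seed=p["seed"],
    )
    genotypes = methylome = covariates = truth = None
    smoothed = None

    if "simulate" in stages:
        genotypes, methylome, covariates, _, truth = simdata.simulate_dataset(sim)
        vcf_path = os.path.join(out, "genotypes.vcf")
        simdata.write_vcf(genotypes, vcf_path)
        emit("vcf", vcf_path)
        cov_path = os.path.join(out, "covariates.tsv")
        covariates.to_csv(cov_path, sep="\t")
        emit("covariates", cov_path)
        manifest["counts"]["n_snps"] = genotypes.n_snps
        manifest["counts"]["n_sites"] = methylome.n_sites

    if "preprocess" in stages and methylome is not None:
        before = methylome.n_sites
        cpg = methio.filter_cpg(methylome, min_cov=p["min_cov_cpg"])
        manifest["counts"]["sites_pre_filter"] = before
        manifest["counts"]["sites_post_filter"] = cpg.n_sites
        methylome = methio.smooth_methylome(
            cpg, min_sites=p["smooth_min_sites"], min_width=p["smooth_min_width"]
        )
        smoothed = methylome.smoothed

    pcs = None
    if "variance" in stages and smoothed is not None:
        n_pcs = p["n_pcs"] or min(28, p["n_samples"] // 6)
        res = varstruct.pca(smoothed, n_components=n_pcs)
        pcs = res.scores
        pca_path = os.path.join(out, "pca_scores.tsv")
        pd.DataFrame(pcs, columns=[f"PC{i+1}" for i in range(pcs.shape[1])]).to_csv(
            pca_path, sep="\t", index=False
        )
        emit("pca_scores", pca_path)

    scanner = None
    if "scan" in stages and smoothed is not None:
        scanner = meqtl.MeQtlScanner(
            window=p["window"], p_keep=p["p_keep"], q_level=p["fdr"], covariates=pcs
        ).fit(genotypes, methylome)
        pairs_path = os.path.join(out, "pairs.tsv")
        cols = ["snp", "chrom", "pos", "context", "slope", "se", "t", "p", "q", "cis_flag"]
        scanner.pairs_[cols].to_csv(pairs_path, sep="\t", index=False, float_format="%.6g")
        emit("pairs", pairs_path)
        manifest["counts"]["n_tests"] = scanner.n_tests_
        manifest["counts"]["n_significant"] = int(len(scanner.significant_))

    regions = []
    if "gdmr" in stages and scanner is not None:
        for snp, grp in scanner.pairs_.groupby("snp", sort=False):
            grp = grp.sort_values("pos")
            regions.extend(
                gdmr.find_gdmrs(
                    grp["t"].to_numpy(),
                    grp["pos"].to_numpy(),
                    pvals=grp["p"].to_numpy(),
                    snp=str(snp),
                    chrom=str(grp["chrom"].iloc[0]),
                    cutoff=p["t_cutoff"],
                    maxgap=p["maxgap"],
                    min_sites=p["min_region_sites"],
                )
            )
        bed_path = os.path.join(out, "gdmrs.bed")
        gdmr.gdmrs_to_bed(regions, bed_path)
        emit("gdmrs_bed", bed_path)
        tsv_path = os.path.join(out, "gdmrs.tsv")
        gdmr.gdmrs_to_frame(regions).to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
        emit("gdmrs", tsv_path)
        manifest["counts"]["n_gdmrs"] = len(regions)

    if "sharing" in stages and scanner is not None and len(scanner.significant_) > 0:
        est = sharing.pi1_sharing(scanner.significant_, scanner.pairs_)
        share_path = os.path.join(out, "pi1.json")
        with open(share_path, "w") as fh:
            json.dump(
                {"pi0": est.pi0, "pi1": est.pi1, "method": est.method, "n": est.n_pvalues},
                fh,
                indent=2,
            )
        emit("pi1", share_path)

    if "diffmeth" in stages and smoothed is not None:
        design = np.column_stack(
            [
                np.ones(p["n_samples"]),
                (covariates["diagnosis"] == "case").to_numpy(dtype=float),
                covariates["age"].to_numpy(),
                (covariates["sex"] == "M").to_numpy(dtype=float),
                covariates["batch"].to_numpy(dtype=float),
                covariates["neuronal_fraction"].to_numpy(),
            ]
        )
        dm = diffmeth.ModeratedDiffMeth(coef_idx=1).fit(design, smoothed)
        dm_path = os.path.join(out, "diffmeth.tsv")
        dm.results_frame(methylome.sites).to_csv(dm_path, sep="\t", index=False, float_format="%.6g")
        emit("diffmeth", dm_path)
        manifest["counts"]["diffmeth_fdr05"] = int((dm.q_ < 0.05).sum())

    if "herit" in stages and genotypes is not None:
        grm = herit.compute_grm(genotypes.dosage, genotypes.samples)
        kept = herit.prune_related(grm, threshold=p["relatedness_threshold"])
        manifest["counts"]["samples_after_pruning"] = int(kept.size)

    manifest["status"] = "complete"
    man_path = os.path.join(out, "manifest.json")
    with open(man_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
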