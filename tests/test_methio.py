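"""I/O round-trips, site filters against brute-force re-evaluation,
blacklist coordinate conventions, and the local smoother."""

import numpy as np
import pandas as pd
import pytest

from methquake import methio, simdata
from methquake.methio import MethylomeMatrix


def _toy_matrix(n_sites=5, n_samples=2, context="CpG", seed=0):
    rng = np.random.default_rng(seed)
    cov = rng.integers(1, 20, size=(n_sites, n_samples))
    meth = rng.binomial(cov, 0.5)
    sites = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, n_sites + 1) * 100,
            "context": context,
            "strand": "unknown",
        }
    )
    return MethylomeMatrix(
        sites=sites,
        samples=[f"S{i}" for i in range(n_samples)],
        methylated=meth,
        coverage=cov,
    )


def test_matrix_invariant_methylated_le_coverage():
    m = _toy_matrix()
    with pytest.raises(ValueError, match="exceeds coverage"):
        MethylomeMatrix(
            sites=m.sites,
            samples=m.samples,
            methylated=m.coverage + 1,
            coverage=m.coverage,
        )


def test_read_write_round_trip(tmp_path):
    m = _toy_matrix(n_sites=30, n_samples=3, seed=1)
    paths = {s: str(tmp_path / f"{s}.cov") for s in m.samples}
    methio.write_methylome(m, paths)
    back = methio.read_methylome(paths)
    assert back.samples == m.samples
    np.testing.assert_array_equal(back.methylated, m.methylated)
    np.testing.assert_array_equal(back.coverage, m.coverage)
    np.testing.assert_array_equal(back.sites["pos"].to_numpy(), m.sites["pos"].to_numpy())


def test_read_methylome_rejects_meth_gt_coverage(tmp_path):
    path = tmp_path / "bad.cov"
    path.write_text("chr1\t100\t100\t140.0\t7\t-2\tCpG\n")
    with pytest.raises(ValueError, match="line 1"):
        methio.read_methylome({"S0": str(path)})


def test_read_methylome_unions_site_universes(tmp_path):
    a = tmp_path / "a.cov"
    b = tmp_path / "b.cov"
    a.write_text("chr1\t100\t100\t50.0\t5\t5\tCpG\nchr1\t200\t200\t0.0\t0\t8\tCpG\n")
    b.write_text("chr1\t100\t100\t100.0\t4\t0\tCpG\n")
    m = methio.read_methylome({"A": str(a), "B": str(b)})
    assert m.n_sites == 2
    # site 200 missing from B: coverage 0 there
    assert m.coverage[1, 1] == 0


def test_filter_cpg_rule_and_idempotence(small_dataset):
    _, methylome, _, _, _ = small_dataset
    out = methio.filter_cpg(methylome, min_cov=3)
    # brute-force oracle: mean coverage across samples >= 3 and context CpG
    expected = [
        i
        for i in range(methylome.n_sites)
        if methylome.sites["context"].iloc[i] == "CpG"
        and methylome.coverage[i].mean() >= 3
    ]
    assert list(out.sites.index) == list(range(len(expected)))
    np.testing.assert_array_equal(
        out.sites["pos"].to_numpy(), methylome.sites["pos"].to_numpy()[expected]
    )
    twice = methio.filter_cpg(out, min_cov=3)
    assert twice.n_sites == out.n_sites


def test_filter_cpg_boundary_cases():
    sites = pd.DataFrame(
        {"chrom": "chr1", "pos": [10, 20], "context": "CpG", "strand": "unknown"}
    )
    cov = np.array([[3, 3, 3], [0, 0, 0]])
    m = MethylomeMatrix(
        sites=sites, samples=["a", "b", "c"], methylated=np.zeros_like(cov), coverage=cov
    )
    out = methio.filter_cpg(m, min_cov=3)
    assert list(out.sites["pos"]) == [10]  # exactly at threshold retained; zeros dropped


def test_filter_cph_rule_and_oracle(rng):
    n_sites, n_samples = 200, 8
    cov = rng.integers(0, 12, size=(n_sites, n_samples))
    meth = rng.binomial(cov, 0.2)
    sites = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, n_sites + 1),
            "context": "CpH",
            "strand": "unknown",
        }
    )
    m = MethylomeMatrix(sites=sites, samples=list("abcdefgh"), methylated=meth, coverage=cov)
    out = methio.filter_cph(m)
    expected = [
        i
        for i in range(n_sites)
        if np.mean((cov[i] > 3) & (meth[i] > 0)) >= 0.5
    ]
    np.testing.assert_array_equal(out.sites["pos"].to_numpy(), np.array(expected) + 1)

    # 4 samples, methylated in 2 with coverage 5 -> retained; in 1 of 4 -> dropped
    cov4 = np.array([[5, 5, 5, 5], [5, 5, 5, 5]])
    meth4 = np.array([[1, 1, 0, 0], [1, 0, 0, 0]])
    sites4 = pd.DataFrame(
        {"chrom": "chr1", "pos": [1, 2], "context": "CpH", "strand": "unknown"}
    )
    m4 = MethylomeMatrix(
        sites=sites4, samples=list("wxyz"), methylated=meth4, coverage=cov4
    )
    assert list(methio.filter_cph(m4).sites["pos"]) == [1]


def test_blacklist_coordinate_convention_and_oracle(rng, tmp_path):
    sites = pd.DataFrame(
        {"chrom": "chr1", "pos": [100, 101], "context": "CpG", "strand": "unknown"}
    )
    bl = pd.DataFrame({"chrom": ["chr1"], "start": [99], "end": [100]})
    keep = methio.exclude_blacklist(sites, bl)
    assert list(keep) == [False, True]  # [99,100) covers 1-based 100 only

    # empty blacklist is the identity
    assert methio.exclude_blacklist(sites, bl.iloc[0:0]).all()

    # random fixture vs brute-force double loop
    n = 400
    s = pd.DataFrame(
        {
            "chrom": rng.choice(["chr1", "chr2"], size=n),
            "pos": rng.integers(1, 2000, size=n),
            "context": "CpG",
            "strand": "unknown",
        }
    )
    starts = rng.integers(0, 1900, size=50)
    iv = pd.DataFrame(
        {
            "chrom": rng.choice(["chr1", "chr2"], size=50),
            "start": starts,
            "end": starts + rng.integers(1, 100, size=50),
        }
    )
    got = methio.exclude_blacklist(s, iv)
    for i in range(n):
        covered = any(
            iv["chrom"].iloc[k] == s["chrom"].iloc[i]
            and iv["start"].iloc[k] < s["pos"].iloc[i] <= iv["end"].iloc[k]
            for k in range(len(iv))
        )
        assert got[i] == (not covered)

    bad = tmp_path / "bad.bed"
    bad.write_text("chr1\t10\n")
    with pytest.raises(ValueError, match="line 1"):
        methio.read_bed(str(bad))


def test_smoother_constant_fixed_point(rng):
    pos = np.sort(rng.choice(200_000, size=500, replace=False)) + 1
    cov = np.full(500, 20.0)
    meth = 0.7 * cov
    sm = methio.smooth_sample(meth, cov, pos)
    assert np.max(np.abs(sm - 0.7)) < 1e-6


def test_smoother_matches_independent_wls_oracle(rng):
    """Interior site value equals a standalone weighted least-squares fit."""
    n = 300
    pos = np.sort(rng.choice(100_000, size=n, replace=False)) + 1
    cov = rng.integers(1, 30, size=n).astype(float)
    meth = rng.binomial(cov.astype(int), 0.6).astype(float)
    sm = methio.smooth_sample(meth, cov, pos, min_sites=70, min_width=2000)
    frac = meth / cov

    for i in (80, 150, 231):
        # oracle: minimal symmetric half-width via explicit expanding search
        h = 0
        while ((pos >= pos[i] - h) & (pos <= pos[i] + h)).sum() < 70:
            h += 1
        h = max(h, 1000)
        inside = (pos >= pos[i] - h) & (pos <= pos[i] + h)
        x = (pos[inside] - pos[i]).astype(float)
        w = (1 - np.clip(np.abs(x / h), 0, 1) ** 3) ** 3 * cov[inside]
        X = np.column_stack([np.ones(x.size), x])
        W = np.diag(w)
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ frac[inside])
        assert sm[i] == pytest.approx(float(np.clip(beta[0], 0, 1)), abs=1e-8)


def test_smoother_imputes_zero_coverage_sites(rng):
    pos = np.arange(1, 301) * 50
    cov = np.full(300, 15.0)
    cov[100] = 0.0
    meth = 0.5 * cov
    sm = methio.smooth_sample(meth, cov, pos)
    assert abs(sm[100] - 0.5) < 1e-6


def test_smoother_locality(rng):
    """Appending distant sites leaves interior smoothed values unchanged."""
    pos = np.sort(rng.choice(50_000, size=200, replace=False)) + 1
    cov = rng.integers(5, 25, size=200).astype(float)
    meth = rng.binomial(cov.astype(int), 0.4).astype(float)
    base = methio.smooth_sample(meth, cov, pos)
    far_pos = np.concatenate([pos, pos[-1] + 500_000 + np.arange(100) * 37])
    far_cov = np.concatenate([cov, np.full(100, 10.0)])
    far_meth = np.concatenate([meth, np.full(100, 9.0)])
    ext = methio.smooth_sample(far_meth, far_cov, far_pos)
    np.testing.assert_allclose(ext[50:150], base[50:150], atol=1e-12)


def test_smoothing_reduces_mse_on_sigmoid_truth(rng):
    """Smoothed values beat raw fractions in MSE against a smooth step."""
    n = 400
    pos = np.arange(n) * 25 + 1
    truth = 0.2 + 0.6 / (1 + np.exp(-(pos - pos[n // 2]) / 1000.0))
    wins = 0
    reps = 30
    for _ in range(reps):
        cov = rng.poisson(15, size=n) + 1
        meth = rng.binomial(cov, truth)
        raw = meth / cov
        sm = methio.smooth_sample(meth.astype(float), cov.astype(float), pos)
        if np.mean((sm - truth) ** 2) < np.mean((raw - truth) ** 2):
            wins += 1
    assert wins == reps


def test_read_genotypes_filters(tmp_path):
    # build a VCF: one good SNP, one rare, one high-missing, one HWE-violating
    n = 100
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr1>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(f"S{i}" for i in range(n)),
    ]
    good = ["0/0"] * 40 + ["0/1"] * 40 + ["1/1"] * 20
    rare = ["0/1"] * 4 + ["0/0"] * 96  # alt freq 0.02
    missing = ["./."] * 15 + ["0/1"] * 45 + ["0/0"] * 40
    hwe_bad = ["0/0"] * 50 + ["1/1"] * 50  # no hets: chi-square p << 1e-6
    for pos, rid, gts in [
        (100, "good", good),
        (200, "rare", rare),
        (300, "missing", missing),
        (400, "hwe", hwe_bad),
    ]:
        lines.append(f"chr1\t{pos}\t{rid}\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(gts))
    path = tmp_path / "test.vcf"
    path.write_text("\n".join(lines) + "\n")
    g = methio.read_genotypes(str(path))
    assert g.snp_ids == ["good"]
    assert g.dosage.shape == (100, 1)
    assert abs(g.dosage.mean() - 0.8) < 1e-9

    # hand-computed HWE chi-square for 50/0/50: expected 25/50/25
    p = methio.hwe_pvalue(50, 0, 50)
    assert p < 1e-20


def test_vcf_round_trip_with_simulator(tmp_path):
    cfg = simdata.SimConfig(n_samples=60, n_snps=30, n_cpg=10, maf_range=(0.2, 0.5), seed=3)
    g = simdata.simulate_genotypes(cfg)
    path = tmp_path / "sim.vcf"
    simdata.write_vcf(g, str(path))
    back = methio.read_genotypes(str(path), maf_min=0.0, hwe_p_min=0.0)
    kept = [g.snp_ids.index(s) for s in back.snp_ids]
    np.testing.assert_array_equal(back.dosage, g.dosage[:, kept])
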