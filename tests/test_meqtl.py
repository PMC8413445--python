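"""The association scan: pair enumeration, per-pair OLS against a
normal-equations oracle, FDR machinery, summaries and interactions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methquake import meqtl, methio, simdata
from tests.conftest import brute_force_bh_cutoff


class _Snps:
    def __init__(self, chrom, pos):
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)


def _sites(chrom, pos):
    return pd.DataFrame({"chrom": chrom, "pos": pos, "context": "CpG"})


def test_enumerate_cis_pairs_boundaries():
    snps = _Snps(["chr1"], [100_000])
    sites = _sites(["chr1", "chr1", "chr2"], [120_000, 120_001, 100_000])
    pairs = list(meqtl.enumerate_cis_pairs(snps, sites, window=20_000))
    assert (0, 0) in pairs  # exactly at the window edge: inclusive
    assert (0, 1) not in pairs
    assert all(s != 2 for _, s in pairs)  # other chromosome excluded


def test_enumerate_cis_pairs_matches_brute_force(rng):
    snps = _Snps(
        rng.choice(["chr1", "chr2"], size=40),
        rng.integers(1, 100_000, size=40),
    )
    order = np.lexsort((snps.pos, snps.chrom.astype(str)))
    snps = _Snps(snps.chrom[order], snps.pos[order])
    spos = np.sort(rng.integers(1, 100_000, size=300))
    schrom = np.sort(rng.choice(["chr1", "chr2"], size=300))
    sites = _sites(schrom, spos)
    got = set(meqtl.enumerate_cis_pairs(snps, sites, window=5000))
    brute = {
        (j, s)
        for j in range(40)
        for s in range(300)
        if snps.chrom[j] == schrom[s] and abs(int(snps.pos[j]) - int(spos[s])) <= 5000
    }
    assert got == brute


def test_fit_pair_exact_and_degenerate():
    d = np.array([0.0, 1.0, 2.0] * 10)
    res = meqtl.fit_pair(d, 0.30 + 0.01 * d)
    assert res.slope == pytest.approx(0.01, abs=1e-14)
    assert res.se == pytest.approx(0.0, abs=1e-12)  # residual SS is zero
    assert res.p < 1e-12

    res0 = meqtl.fit_pair(d, np.full(30, 0.4))
    assert res0.slope == 0.0 and res0.t == 0.0

    with pytest.raises(meqtl.PairSkipped, match="constant_dosage"):
        meqtl.fit_pair(np.ones(30), np.random.default_rng(0).random(30))


def test_fit_pair_matches_normal_equations_oracle(rng):
    n = 50
    d = rng.choice([0.0, 1.0, 2.0], size=n)
    C = rng.standard_normal((n, 3))
    y = 0.3 + 0.02 * d + C @ [0.1, -0.2, 0.05] + rng.normal(0, 0.05, n)
    res = meqtl.fit_pair(d, y, C)
    X = np.column_stack([np.ones(n), d, C])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    df = n - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
    t = beta[1] / se
    p = 2 * stats.t.sf(abs(t), df)
    assert res.slope == pytest.approx(beta[1], abs=1e-10)
    assert res.se == pytest.approx(se, abs=1e-10)
    assert res.t == pytest.approx(t, abs=1e-10)
    assert res.df == df
    assert res.p == pytest.approx(p, abs=1e-10)


def test_fit_pair_pairwise_complete_case(rng):
    n = 60
    d = rng.choice([0.0, 1.0, 2.0], size=n)
    y = 0.3 + 0.02 * d + rng.normal(0, 0.01, n)
    d_miss = d.copy()
    d_miss[:10] = np.nan
    res = meqtl.fit_pair(d_miss, y)
    ref = meqtl.fit_pair(d[10:], y[10:])
    assert res.slope == pytest.approx(ref.slope, abs=1e-14)


def test_scan_agrees_with_fit_pair(small_dataset, smoothed_small, rng):
    genotypes, _, covdf, _, _ = small_dataset
    C = np.column_stack([covdf["age"], covdf["neuronal_fraction"]])
    sc = meqtl.MeQtlScanner(window=5000, covariates=C).fit(genotypes, smoothed_small)
    take = rng.choice(len(sc.pairs_), size=25, replace=False)
    for _, row in sc.pairs_.iloc[take].iterrows():
        ref = meqtl.fit_pair(
            genotypes.dosage[:, int(row["snp_idx"])],
            smoothed_small.smoothed[int(row["site_idx"])],
            C,
        )
        assert row["slope"] == pytest.approx(ref.slope, abs=1e-10)
        assert row["t"] == pytest.approx(ref.t, abs=1e-8)
        assert row["p"] == pytest.approx(ref.p, abs=1e-10)


def test_scan_empty_input():
    cfg = simdata.SimConfig(n_samples=20, n_snps=1, n_cpg=50, seed=2)
    g, m, _, _, _ = simdata.simulate_dataset(cfg)
    sm = methio.smooth_methylome(m)
    far = g.take_snps([0])
    far.pos = np.array([10_000_000])  # no sites within window
    sc = meqtl.MeQtlScanner(window=100).fit(far, sm)
    assert len(sc.pairs_) == 0
    assert sc.n_tests_ == 0
    assert sc.fdr_cutoff_ is None


def test_fdr_cutoff_hand_cases():
    p = np.array([0.0001] * 50 + [0.9] * 50)
    assert meqtl.fdr_pvalue_cutoff(p, q_level=0.01) == pytest.approx(0.0001)
    assert meqtl.fdr_pvalue_cutoff(np.full(10, 0.9), q_level=0.01) is None
    assert meqtl.fdr_pvalue_cutoff([0.005], m_total=1, q_level=0.01) == 0.005
    assert meqtl.fdr_pvalue_cutoff([], q_level=0.01) is None


def test_fdr_cutoff_with_implied_tests(rng):
    """Recorded small p-values plus an implied mass of unsaved larger ones."""
    p_small = rng.uniform(0, 1e-4, size=20)
    cut = meqtl.fdr_pvalue_cutoff(p_small, m_total=10_000, q_level=0.01)
    brute = brute_force_bh_cutoff(list(p_small) + [1.0] * 9980, 10_000, 0.01)
    assert cut == pytest.approx(brute)


def test_summarize_snp():
    pairs = pd.DataFrame(
        {
            "snp": ["a", "a", "b"],
            "pos": [100, 20_100, 500],
            "slope": [0.02, -0.04, 0.01],
        }
    )
    out = meqtl.summarize_snp(pairs).set_index("snp")
    assert out.loc["a", "width_bp"] == 20_000
    assert out.loc["a", "n_sites"] == 2
    assert out.loc["a", "mean_abs_slope"] == pytest.approx(0.03)
    assert out.loc["b", "width_bp"] == 0


def test_index_snp_scan_cis_trans_labels():
    cfg = simdata.SimConfig(n_samples=40, n_snps=4, n_cpg=300, chrom_length=600_000, seed=4)
    g, m, _, _, _ = simdata.simulate_dataset(cfg)
    sm = methio.smooth_methylome(m)
    out = meqtl.index_snp_scan(g, sm, [0, 2], cis_window=250_000)
    assert set(out["snp_idx"]) <= {0, 2}
    # every tested site present with a p-value (cutoff 1)
    n_chr_sites = (sm.sites["chrom"] == g.chrom[0]).sum()
    assert (out["snp_idx"] == 0).sum() == n_chr_sites
    # oracle labels
    for _, row in out.iterrows():
        j = int(row["snp_idx"])
        expected = (
            "cis"
            if row["chrom"] == g.chrom[j] and abs(row["pos"] - g.pos[j]) <= 250_000
            else "trans"
        )
        assert row["cis_flag"] == expected


def test_cis_label_boundary():
    class GS:
        pass

    g = GS()
    g.n_snps = 1
    g.snp_ids = ["s"]
    g.chrom = np.array(["chr1"], dtype=object)
    g.pos = np.array([1_000_000])
    g.dosage = np.tile([0.0, 1.0, 2.0], 20)[:, None]
    sites = _sites(["chr1", "chr1"], [1_250_000, 1_250_001])
    values = np.random.default_rng(0).random((2, 60))
    out = meqtl.scan_frame(g, sites, values, all_sites=True, cis_window=250_000)
    flags = out.sort_values("pos")["cis_flag"].tolist()
    assert flags == ["cis", "trans"]


def test_interaction_fit_construction_and_oracle(rng):
    n = 90
    d = rng.choice([0.0, 1.0, 2.0], size=n)
    age = rng.uniform(20, 80, size=n)
    y = 0.3 + 0.001 * d * age
    res = meqtl.interaction_fit(d, y, age)
    assert res.slope == pytest.approx(0.001, abs=1e-12)

    y2 = y + rng.normal(0, 0.02, n)
    res2 = meqtl.interaction_fit(d, y2, age)
    X = np.column_stack([np.ones(n), d, age, d * age])
    beta = np.linalg.solve(X.T @ X, X.T @ y2)
    resid = y2 - X @ beta
    sigma2 = resid @ resid / (n - 4)
    se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[3, 3])
    assert res2.slope == pytest.approx(beta[3], abs=1e-10)
    assert res2.se == pytest.approx(se, abs=1e-10)

    with pytest.raises(ValueError, match="constant"):
        meqtl.interaction_fit(d, y, np.ones(n))


def test_interaction_scan_agrees_with_interaction_fit(small_dataset, smoothed_small):
    genotypes, _, covdf, _, _ = small_dataset
    mod = covdf["age"].to_numpy()
    out = meqtl.interaction_scan(genotypes, smoothed_small, mod, window=3000)
    assert len(out) > 0
    for _, row in out.head(20).iterrows():
        ref = meqtl.interaction_fit(
            genotypes.dosage[:, int(row["snp_idx"])],
            smoothed_small.smoothed[int(row["site_idx"])],
            mod,
        )
        assert row["t"] == pytest.approx(ref.t, abs=1e-8)


def test_orthogonal_covariate_changes_only_df(rng):
    """A covariate orthogonal to dosage and methylation alters t only through
    the residual-df change."""
    n = 200
    d = rng.choice([0.0, 1.0, 2.0], size=n)
    y = 0.4 + 0.01 * d + rng.normal(0, 0.03, n)
    base = meqtl.fit_pair(d, y)
    # build a covariate orthogonal to [1, d, y]
    raw = rng.standard_normal(n)
    Q, _ = np.linalg.qr(np.column_stack([np.ones(n), d, y]))
    orth = raw - Q @ (Q.T @ raw)
    ext = meqtl.fit_pair(d, y, orth)
    assert ext.df == base.df - 1
    # slope identical; t scales by sqrt(df ratio) through sigma^2 = RSS/df
    assert ext.slope == pytest.approx(base.slope, abs=1e-12)
    assert ext.t == pytest.approx(base.t * np.sqrt(ext.df / base.df), rel=1e-10)


def test_scan_output_order_is_position_sorted(small_dataset, smoothed_small):
    genotypes, *_ = small_dataset
    sc = meqtl.MeQtlScanner(window=4000).fit(genotypes, smoothed_small)
    pos = sc.pairs_["pos"].to_numpy()
    assert np.all(np.diff(pos) >= 0)
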