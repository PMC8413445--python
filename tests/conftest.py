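import numpy as np
import pytest

from methquake import methio, simdata, varstruct


@pytest.fixture(scope="session")
def small_config():
    return simdata.SimConfig(
        n_samples=80, n_snps=60, n_cpg=800, chrom_length=40_001, seed=11
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """Genotypes, methylome with counts, covariates, true fractions, truth."""
    return simdata.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def smoothed_small(small_dataset):
    _, methylome, _, _, _ = small_dataset
    return methio.smooth_methylome(methio.filter_cpg(methylome))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def brute_force_bh_cutoff(pvals, m, q):
    """Hand-run BH step-up: largest p(i) with p(i) <= q*i/m."""
    p = sorted(pvals)
    best = None
    for i, v in enumerate(p, start=1):
        if v <= q * i / m:
            best = v
    return best


def brute_force_bh_adjust(pvals):
    """Textbook BH adjusted values via the step-up recursion."""
    import numpy as np

    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adj[i] = val
        prev = val
    return adj
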