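import numpy as np
import pytest

from multimagma.simulate import FixtureSpec, simulate_reference_panel, simulate_summary_stats


@pytest.fixture(scope="session")
def tiny_truth():
    """Small simulated panel shared by fast tests: 6 genes x 5 SNPs, n=300."""
    spec = FixtureSpec(
        n_individuals=300, n_genes=6, snps_per_gene=5, block_rho=0.5,
        maf_range=(0.2, 0.5), seed=7,
    )
    return simulate_reference_panel(spec)


@pytest.fixture(scope="session")
def tiny_sumstats(tiny_truth):
    return simulate_summary_stats(tiny_truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
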