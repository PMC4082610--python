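import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from asconsv.io_coverage import StrandedCoverage
from asconsv.pipeline import analyze
from asconsv.synthetic import SimulationConfig, simulate

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_coverage(plus: np.ndarray, minus: np.ndarray | None = None, chrom: str = "chrI") -> StrandedCoverage:
    """StrandedCoverage from explicit depth arrays (test helper)."""
    plus = np.asarray(plus, dtype=np.int64)
    minus = (
        np.zeros_like(plus) if minus is None else np.asarray(minus, dtype=np.int64)
    )
    cov = StrandedCoverage({chrom: len(plus)})
    cov.depth[chrom]["+"] = plus
    cov.depth[chrom]["-"] = minus
    cov.total_mapped_bases = int(plus.sum() + minus.sum())
    return cov


@pytest.fixture(scope="session")
def sim_small():
    """A 40-gene two-species simulation shared across tests."""
    return simulate(SimulationConfig(seed=11, n_genes=40))


@pytest.fixture(scope="session")
def analysis_small(sim_small):
    covs = {k: sim_small.coverage(*k) for k in sim_small.fragments}
    return analyze(
        covs,
        sim_small.fragments,
        sim_small.annotations,
        sim_small.truth.homology,
    )
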