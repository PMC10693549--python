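import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from methtrio.core import Thresholds, Trio, TrioSet
from methtrio.matrix import MethMatrix, site_ids
from methtrio.pipeline import PipelineConfig, run_pipeline
from methtrio.simulate import SimConfig, simulate_dataset

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


SMALL_SIM = SimConfig(
    seed=3,
    n_stable=200,
    n_cis_mqtl=10,
    n_trans_mqtl=10,
    n_heritable=10,
    n_non_mendelian=10,
    n_imprinted=6,
    n_background_snps=40,
    chrom_length=1_000_000,
)

# low-noise, high-coverage study conditions used for parameter recovery
RECOVERY_SIM = SimConfig(seed=7, mean_coverage=150.0, noise_sd=1.0)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(SMALL_SIM)


@pytest.fixture(scope="session")
def recovery_bundle():
    """Full pipeline run at the parameter-recovery study conditions."""
    return run_pipeline(PipelineConfig(sim=RECOVERY_SIM))


@pytest.fixture
def thresholds():
    return Thresholds()


@pytest.fixture
def toy_trios():
    return TrioSet([
        Trio("F1", "f1", "m1", "c1"),
        Trio("F2", "f2", "m2", "c2"),
        Trio("F3", "f3", "m3", "c3"),
        Trio("F4", "f4", "m4", "c4"),
    ])


def make_meth_matrix(rows, samples, chrom="chr1", start=1000, cov_value=20):
    """Toy MethMatrix from a list of per-site percent lists (None=missing)."""
    n = len(rows)
    meth = np.full((n, len(samples)), np.nan)
    cov = np.zeros((n, len(samples)), dtype=int)
    for i, row in enumerate(rows):
        for j, v in enumerate(row):
            if v is not None:
                meth[i, j] = v
                cov[i, j] = cov_value
    sites = pd.DataFrame({
        "chrom": [chrom] * n,
        "pos": [start + 100 * i for i in range(n)],
    })
    sites.index = site_ids(sites["chrom"], sites["pos"])
    return MethMatrix(sites=sites, meth=meth, cov=cov, samples=list(samples))


@pytest.fixture
def toy_samples():
    return ["f1", "m1", "c1", "f2", "m2", "c2",
            "f3", "m3", "c3", "f4", "m4", "c4"]
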