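import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import snpbarcode as sb

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def steroid_table():
    return sb.load_steroid_snps()


@pytest.fixture(scope="session")
def fixture_dataset(steroid_table):
    """One simulated 5000/5000 dataset from the bundled 23-SNP table."""
    return sb.simulate_dataset(steroid_table, seed=1)


@pytest.fixture(scope="session")
def toy_dataset():
    """Deterministic 6-SNP, 40-case/40-control dataset for oracle checks."""
    rng = np.random.default_rng(12345)
    return sb.GenotypeDataset(
        case_matrix=rng.integers(1, 4, size=(40, 6)).astype(np.int8),
        control_matrix=rng.integers(1, 4, size=(40, 6)).astype(np.int8),
        snp_ids=tuple(f"snp{i}" for i in range(1, 7)),
    )


@pytest.fixture(scope="session")
def planted_dataset():
    """4-SNP dataset with a unique planted 2-SNP protective signal.

    SNPs(1-2)-genotypes(1-1) is carried by 80 controls but only 5 cases;
    the remaining entries are random with no built-in structure, so the
    planted pair dominates every other barcode by a wide margin.
    """
    rng = np.random.default_rng(777)
    n = 120
    case = rng.integers(1, 4, size=(n, 4)).astype(np.int8)
    control = rng.integers(1, 4, size=(n, 4)).astype(np.int8)
    # erase accidental carriers, then plant the exact carrier counts
    for m, k in ((case, 5), (control, 80)):
        carriers = (m[:, 0] == 1) & (m[:, 1] == 1)
        m[carriers, 0] = 2
        m[:k, 0] = 1
        m[:k, 1] = 1
    return sb.GenotypeDataset(
        case_matrix=case,
        control_matrix=control,
        snp_ids=("s1", "s2", "s3", "s4"),
    )
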