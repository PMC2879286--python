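import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from parallgwa.genotype_io import GenotypeMatrix, SNPInfo
from parallgwa.synthetic_data import SimSpec, simulate_genotypes

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_matrix(codes, chrom="1", spacing=1000):
    """Build a GenotypeMatrix from a plain nested list (None = missing)."""
    arr = np.array(
        [[-1 if c is None else c for c in row] for row in codes], dtype=np.int8
    )
    n, m = arr.shape
    snps = [
        SNPInfo(f"snp{j}", chrom, (j + 1) * spacing, "A", "G") for j in range(m)
    ]
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)], snps=snps, codes=arr
    )


@pytest.fixture
def tiny_gm():
    # 5 samples x 4 SNPs with deliberate missing cells
    return make_matrix(
        [
            [0, 1, 2, 0],
            [0, 1, 0, None],
            [1, 1, 1, 2],
            [2, None, 0, 0],
            [None, 0, 2, 1],
        ]
    )


@pytest.fixture(scope="session")
def sim_gm():
    """Shared mid-size simulated panel (120 x 80, 3% missing)."""
    return simulate_genotypes(
        SimSpec(n_ind=120, n_snp=80, mafs=0.3, missing_rate=0.03, seed=42)
    )
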