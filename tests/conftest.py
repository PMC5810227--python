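import numpy as np
import pandas as pd
import pytest

from gbrecall import CohortSpec, GenotypeMatrix, MarkerSpec, simulate_genotypes


def make_matrix(calls, rsids=None, sample_ids=None) -> GenotypeMatrix:
    """Small hand-built genotype matrix with boilerplate metadata."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    rsids = rsids or [f"rs{j}" for j in range(m)]
    sample_ids = sample_ids or [f"P{i:03d}" for i in range(n)]
    markers = pd.DataFrame(
        {
            "chromosome": 1,
            "position": [100 * (j + 1) for j in range(m)],
            "minor_allele": "A",
            "major_allele": "G",
        },
        index=pd.Index(rsids, name="rsID"),
    )
    return GenotypeMatrix(calls, np.array(sample_ids, dtype=object), markers)


@pytest.fixture(scope="session")
def clean_cohort() -> GenotypeMatrix:
    """300 samples x 2,000 HWE markers, one subpopulation, no defects.

    Enough markers that the moment-based relatedness estimates of unrelated
    pairs (noise SD ~ 1/sqrt(markers)) sit far below the pruning threshold.
    """
    spec = CohortSpec(
        n_samples=300,
        markers=tuple(MarkerSpec(maf=m) for m in np.linspace(0.05, 0.5, 2000)),
        seed=11,
    )
    return simulate_genotypes(spec)


@pytest.fixture(scope="session")
def recall_pool() -> pd.DataFrame:
    """Covariate pool for matching tests: ages, sexes, no exclusions."""
    rng = np.random.default_rng(5)
    n = 600
    return pd.DataFrame(
        {
            "age": rng.uniform(45, 75, n),
            "sex": rng.integers(0, 2, n),
            "anticoagulant_flag": False,
            "lipid_lowering_flag": False,
            "diabetes_flag": False,
        },
        index=pd.Index([f"P{i:04d}" for i in range(n)], name="sample_id"),
    )
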