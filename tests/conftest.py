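import numpy as np
import pytest

from cgpatch import synth
from cgpatch.genotypes import GenotypeMatrix


@pytest.fixture(scope="session")
def small_study() -> synth.SyntheticDataset:
    """Four cohorts of 8 at 1500 common SNPs, one single-mother family cohort."""
    return synth.make_study_like_dataset(
        {
            "n_cohorts": 4,
            "cohort_size": 8,
            "sweepstake_cohorts": ["coh02"],
            "L": 1500,
            "founder_dist": "uniform",
            "founder_params": (0.05, 0.95),
        },
        seed=123,
    )


def matrix_from_rows(rows, cohorts=None) -> GenotypeMatrix:
    """Helper: build a GenotypeMatrix from a list of dosage rows."""
    rows = np.asarray(rows, dtype=np.int8)
    n = rows.shape[0]
    cohorts = cohorts or ["c0"] * n
    return GenotypeMatrix(
        dosages=rows,
        samples=[f"s{i}" for i in range(n)],
        cohorts=np.array(cohorts, dtype=object),
    )
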