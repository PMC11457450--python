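import numpy as np
import pandas as pd
import pytest

import apakit


@pytest.fixture(scope="session")
def mutation_diff():
    """A differential-APA table from a mutation cohort with planted targets.

    Shared by enrichment tests; 2000 genes, 500 lengthened targets.
    """
    targets = [f"T{i:04d}" for i in range(500)]
    utr, maf, truth = apakit.simulate_mutation_cohort(
        n_samples=120, lof_fraction=0.5, target_genes=targets,
        delta=2.0, n_genes=2000, seed=101,
    )
    groups = apakit.stratify_by_mutation(maf, roster=utr.samples)
    diff = apakit.test_differential_apa(utr, groups)
    return diff, truth


@pytest.fixture
def small_matrix():
    data = pd.DataFrame(
        [[1.0, 2.0], [3.0, np.nan], [5.0, 6.0]],
        index=["g1", "g2", "g3"], columns=["s1", "s2"],
    )
    return apakit.GeneSampleMatrix(data, tag="utr_metric", dialect="length_like")
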