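import numpy as np
import pandas as pd
import pytest

import osnpipe as op
from osnpipe.mixture import EMConfig
from osnpipe.simulate import generate_reference_cellcycle, cellcycle_gene_ids


@pytest.fixture(scope="session")
def cohort21():
    """The 21-cell preset (19 canonical + 2 type B), seed 1."""
    return op.generate_cohort(op.preset_config("cohort21", seed=1))


@pytest.fixture(scope="session")
def cohort21_normalized(cohort21):
    factors = op.size_factors(cohort21.counts, min_mean=1.0)
    normalized = op.normalize(cohort21.counts.drop_spikeins(), factors)
    return factors, normalized


@pytest.fixture(scope="session")
def cohort21_calls(cohort21, cohort21_normalized):
    _, normalized = cohort21_normalized
    calls, fit = op.call_receptors(
        normalized, cohort21.coverage, cohort21.annotation, EMConfig(seed=1)
    )
    return calls, fit


@pytest.fixture(scope="session")
def cellcycle_model():
    cfg = op.preset_config("cohort21", seed=1)
    ref, labels = generate_reference_cellcycle(cfg)
    return op.train_cellcycle(ref, labels, cellcycle_gene_ids(cfg))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_counts():
    """Tiny deterministic count matrix for IO and normalization checks."""
    return pd.DataFrame(
        [[10, 20], [20, 40], [30, 60]],
        index=["gA", "gB", "gC"],
        columns=["s1", "s2"],
    )
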