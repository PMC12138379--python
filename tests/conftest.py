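import numpy as np
import pandas as pd
import pytest

from hccomics import CohortConfig, generate_cohort


def log2_tpm(tpm: pd.DataFrame) -> pd.DataFrame:
    return np.log2(tpm + 1.0)


@pytest.fixture(scope="session")
def small_bundle():
    """Small seeded cohort shared across read-only tests."""
    cfg = CohortConfig(
        n_tumor=60, n_normal=10, n_genes=40, probes_per_gene=2,
        n_decoy_probes=6, n_normal_methylated_probes=4,
        planted_silenced_genes=2, planted_mutations=2,
        background_mutations=5, n_prognostic_genes=3, seed=3,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
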