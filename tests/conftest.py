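"""Shared fixtures: small architectures and datasets built at test time."""

import numpy as np
import pytest

from epiomb import (
    DiseaseArchitecture,
    build_pure_epistasis_model,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def arch_2and2_balanced():
    """Two independent two-locus components, equal case mix, 20 SNPs."""
    m = build_pure_epistasis_model(2, 0.01)
    return DiseaseArchitecture(
        components=((m, (0, 1)), (m, (2, 3))),
        case_mix=(0.5, 0.5),
        n_snps=20,
        scenario_id="20snp_2&2_1:1",
    )


@pytest.fixture(scope="session")
def dataset_2and2(arch_2and2_balanced):
    """One balanced 1,600-sample dataset with two planted interactions."""
    return simulate_dataset(arch_2and2_balanced, 800, 800, seed=20240)


@pytest.fixture()
def rng():
    return np.random.default_rng(987654321)
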