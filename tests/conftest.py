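import numpy as np
import pytest

from paracons import (
    CohortSpec,
    FamilySimConfig,
    MutationRateTable,
    PropertyTable,
    simulate_family,
    trivial_msa,
)


@pytest.fixture(scope="session")
def property_table() -> PropertyTable:
    return PropertyTable.default()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def uniform_rates() -> MutationRateTable:
    return MutationRateTable.uniform(1e-8)


@pytest.fixture(scope="session")
def ndd_cohort() -> CohortSpec:
    return CohortSpec("NDD", 10068)


@pytest.fixture()
def sim_family():
    """Small two-block family: conserved core + variable linker."""
    cfg = FamilySimConfig(
        n_genes=4,
        blocks=[(30, 0.02), (30, 0.6)],
        family_id="fam1",
        seed=11,
    )
    sim = simulate_family(cfg)
    return sim


@pytest.fixture()
def sim_msa(sim_family):
    return trivial_msa(sim_family.family)
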