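import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from symbiopsi.pseudogene_caller import CallerConfig, call_pseudogenes
from symbiopsi.synthetic_data import CohortConfig, simulate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_config(**overrides) -> CohortConfig:
    """A small, fast cohort configuration for unit tests.

    One taxon per group, short genomes, few families; group-structured
    parameters keep the default contrasts unless overridden.
    """
    base = dict(
        taxa_per_group={"Ev": 1, "S1": 1, "S2": 1, "Po": 1},
        n_families=20,
        genes_per_family_per_taxon=1,
        genome_length=30_000,
        n_scaffolds=2,
        repeat_library_size=2,
        repeat_length=300,
        seed=42,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(make_config())


@pytest.fixture(scope="session")
def default_cohort():
    """The full default cohort: 2 taxa x 4 groups, 200 kb genomes."""
    return simulate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def default_calls(default_cohort):
    """Pseudogene calls for every taxon of the default cohort."""
    cfg = CallerConfig()
    calls = {}
    for taxon in default_cohort.genomes:
        calls[taxon] = call_pseudogenes(
            default_cohort.proteomes[taxon],
            default_cohort.genomes[taxon],
            default_cohort.annotations[taxon],
            cfg,
            taxon=taxon,
        )
    return calls
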