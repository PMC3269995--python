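import numpy as np
import pytest

from radsnp import simulate as sim


@pytest.fixture(scope="session")
def small_params() -> sim.SimParams:
    return sim.SimParams(
        genome_length=200_000,
        pstI_site_spacing=4_000,
        seed=3,
        depth_weights=(1.0, 1.0, 1.0),
        het_rate_per_accession=(0.0005, 0.0005, 0.0005),
        indel_fraction=0.0,
        insert_range=(56, 300),
    )


@pytest.fixture(scope="session")
def small_reference(small_params):
    return sim.simulate_reference(small_params)


@pytest.fixture(scope="session")
def small_world(small_params, small_reference):
    """(params, reference, accessions, truth) for a 200 kb three-accession
    simulation shared across tests."""
    accessions, truth = sim.derive_accessions(small_reference, small_params)
    return small_params, small_reference, accessions, truth


@pytest.fixture(scope="session")
def small_libraries(small_world):
    params, reference, accessions, _ = small_world
    n_per_locus = 72
    n_loci = 2 * len(reference.planted_sites)
    return {
        acc.accession_id: sim.simulate_rad_library(
            acc, params, n_per_locus * n_loci, params.rng(10 + i))
        for i, acc in enumerate(accessions)
    }


@pytest.fixture(scope="session")
def small_pipeline(small_libraries):
    from radsnp import pipeline

    return pipeline.run_read_pipeline(small_libraries)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def random_sequence(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=n))
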