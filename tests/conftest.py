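import numpy as np
import pytest

from mesoimmunity import (
    PhenotypeSimConfig,
    aggregate_replicates,
    assemble_distance_table,
    simulate_clade,
    simulate_immunity,
)
from mesoimmunity.simulate import CladeSimConfig


@pytest.fixture(scope="session")
def small_clade():
    """An 8-taxon simulated clade reused across statistic-level tests."""
    return simulate_clade(
        CladeSimConfig(n_phages=8, genome_length=30_000), seed=11
    )


@pytest.fixture(scope="session")
def small_distances(small_clade):
    models = {t: small_clade.true_motif(t) for t in small_clade.genomes}
    return assemble_distance_table(
        small_clade.genomes,
        motif_models=models,
        proteins={"rep": small_clade.rep_seqs},
        hth_domains={t: small_clade.hth_domain(t) for t in small_clade.genomes},
    )


@pytest.fixture(scope="session")
def small_matrix(small_distances):
    records = simulate_immunity(
        small_distances, PhenotypeSimConfig(), seed=11, include_crs=True
    )
    return aggregate_replicates(records)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
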