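import pytest

from haplopipe import FixtureParams, build_genotype_matrix, merge_reports, simulate_dataset

# small study used where many seeds are iterated
SMALL = dict(ref_length=600, n_individuals=8, n_contigs=3, sites_per_contig=3)


@pytest.fixture(scope="session")
def bundle():
    """Clean diploid study at the default design (no planted errors)."""
    return simulate_dataset(FixtureParams(seed=1))


@pytest.fixture(scope="session")
def noisy_bundle():
    """Same design with planted read conflicts and missing calls."""
    return simulate_dataset(FixtureParams(seed=1, conflict_rate=0.05, missing_rate=0.05))


@pytest.fixture(scope="session")
def haploid_bundle():
    return simulate_dataset(FixtureParams(seed=3, ploidy=1, **SMALL))


@pytest.fixture(scope="session")
def matrix_and_report(bundle):
    call_set = merge_reports(bundle.reports, bundle.reference)
    return build_genotype_matrix(call_set)


def sdat_projection(matrix):
    """The fields SDAT can represent (allele table and reference id are not stored)."""
    return (matrix.ploidy, matrix.positions, matrix.individuals, matrix.calls)
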