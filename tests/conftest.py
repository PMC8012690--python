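import pytest

from nat2kit import data as refdata
from nat2kit.star_allele import load_allele_definitions


@pytest.fixture(scope="session")
def defs():
    return load_allele_definitions("NAT2")


@pytest.fixture(scope="session")
def cohorts():
    """Published genotype counts: Japanese + five 1KGP super-populations."""
    return refdata.load_genotype_counts()


@pytest.fixture(scope="session")
def kinetic_params():
    """Published Km/Vmax/CLint means and SEs per drug x allele."""
    return refdata.load_kinetic_params()


@pytest.fixture(scope="session")
def ref_scores():
    """Published per-drug genotype activity scores."""
    return refdata.load_reference_activity_scores()[0]


@pytest.fixture(scope="session")
def ref_phenotypes():
    """Published per-drug genotype -> phenotype labels."""
    return refdata.load_reference_activity_scores()[1]
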