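import pytest
from hypothesis import settings

from epiquant import ptm_model

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def scheme():
    return ptm_model.DerivatizationScheme()


@pytest.fixture(scope="session")
def h3_sequence():
    return ptm_model.load_h3_sequence()


@pytest.fixture(scope="session")
def h3_peptides(h3_sequence):
    return ptm_model.digest(h3_sequence, blocked_lysines=True, protein_id="H3")


@pytest.fixture(scope="session")
def k27_peptide(h3_peptides):
    return next(p for p in h3_peptides if p.start == 27)


@pytest.fixture(scope="session")
def catalogue():
    return ptm_model.h3_isoform_catalogue()
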