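import pytest

from ptmpatch import PeptideSpec, default_registry, make_peptide


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture()
def ala_ser_ala(registry):
    return make_peptide(PeptideSpec("ASA"), registry)


@pytest.fixture()
def perturbed_tripeptide(registry):
    return make_peptide(PeptideSpec("ASA", perturbation=0.02, seed=42), registry)


@pytest.fixture()
def pdb_text(ala_ser_ala):
    from ptmpatch import write_pdb

    return write_pdb(ala_ser_ala)
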