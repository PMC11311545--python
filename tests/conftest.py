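import pytest

from idmsquant import fixtures


@pytest.fixture(scope="session")
def emd_pair():
    return fixtures.table2_emd_mel_pt()


@pytest.fixture(scope="session")
def mel_solution_series():
    return fixtures.table4_msa_mel()


@pytest.fixture(scope="session")
def cya_solution_series():
    return fixtures.table5_msa_cya()


@pytest.fixture(scope="session")
def pt_sample_series():
    return fixtures.table6_msa_mel_pt()
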