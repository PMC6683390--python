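import pytest

from lumipanel import io as lio
from lumipanel.deconvolution import PriorTable


@pytest.fixture(scope="session")
def clinical():
    """Packaged clinical dataset: (donor_panel, bead_panel, mfi, cutoffs)."""
    return lio.load_clinical_fixture()


@pytest.fixture(scope="session")
def donor_panel(clinical):
    return clinical[0]


@pytest.fixture(scope="session")
def bead_panel(clinical):
    return clinical[1]


@pytest.fixture(scope="session")
def clinical_mfi(clinical):
    return clinical[2]


@pytest.fixture(scope="session")
def clinical_cutoffs(clinical):
    return clinical[3]


@pytest.fixture(scope="session")
def priors():
    return PriorTable.default()


@pytest.fixture(scope="session")
def expected_calls():
    return lio.load_expected_calls()


@pytest.fixture(scope="session")
def gp2b3a(bead_panel):
    """The three-system glycoprotein bead (HPA-1/3/4)."""
    return bead_panel.bead("GPIIbIIIa")
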