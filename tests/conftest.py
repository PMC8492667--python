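import pytest

from optoconsort import models as M
from optoconsort import synthetic_data as S


@pytest.fixture(scope="session")
def core_fm():
    return S.FluorescenceModel.default_core()


@pytest.fixture(scope="session")
def gaudi_fm():
    return S.FluorescenceModel.default_gaudi()


@pytest.fixture(scope="session")
def default_diff():
    return M.DiffParams()


@pytest.fixture(scope="session")
def default_gaudi():
    return M.GaudiParams()
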