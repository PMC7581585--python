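import pytest

from acscea import default_parameters, publication_conventions


@pytest.fixture(scope="session")
def base_params():
    return default_parameters()


@pytest.fixture(scope="session")
def pub_params():
    """Base case under the original spreadsheet's cycle accounting."""
    return publication_conventions(default_parameters())
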