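import pytest

from ptsdcea import builtin_base_case


@pytest.fixture(scope="session")
def base_config():
    return builtin_base_case()


@pytest.fixture(scope="session")
def base_cea(base_config):
    from ptsdcea import run_cea

    return run_cea(base_config)
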