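import pytest

from semrec import default_config, generate_study


@pytest.fixture(scope="session")
def default_cfg():
    return default_config(seed=11)


@pytest.fixture(scope="session")
def study_table(default_cfg):
    """One synthetic study drawn under the default design."""
    return generate_study(default_cfg)
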