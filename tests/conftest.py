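import pytest

from orgatlas import PtsMotifConfig, SimConfig


@pytest.fixture
def motif_config():
    return PtsMotifConfig()


@pytest.fixture
def small_sim_config():
    return SimConfig(seed=11, n_proteins=120, n_genes=60)


def write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


@pytest.fixture
def write_file(tmp_path):
    """Write a small text fixture into the test's tmp dir, return its path."""
    return lambda name, text: write(tmp_path, name, text)
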