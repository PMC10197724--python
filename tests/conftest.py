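import pytest
from hypothesis import settings

from voltime.fixtures import canonical_experiment, generate_toy_dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def toy_dir(tmp_path_factory):
    """Directory holding the generated toy TIFF files (shared, read-only)."""
    d = tmp_path_factory.mktemp("toy")
    generate_toy_dataset(d)
    return d


@pytest.fixture(scope="session")
def toy_experiment(toy_dir):
    """The canonical mapped toy experiment (in-memory query path)."""
    return canonical_experiment(toy_dir)


@pytest.fixture()
def toy_db_experiment(toy_dir, tmp_path):
    """A fresh toy experiment with an attached database (SQL query path)."""
    exp = canonical_experiment(toy_dir)
    exp.save(tmp_path / "exp.db")
    return exp
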