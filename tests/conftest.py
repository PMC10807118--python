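import pytest

from barcodeid import FixtureSpec, load_rsl
from barcodeid.fixtures import write_fixture_set


@pytest.fixture(scope="session")
def benchmark_spec():
    """The small frog-barcoding benchmark layout: 25-lineage library, nine
    in-group queries over seven lineages (three at 4-6% divergence), one
    outgroup."""
    return FixtureSpec(seed=42)


@pytest.fixture(scope="session")
def benchmark_files(benchmark_spec, tmp_path_factory):
    d = tmp_path_factory.mktemp("benchmark")
    return write_fixture_set(benchmark_spec, d)


@pytest.fixture(scope="session")
def benchmark_rsl(benchmark_files):
    return load_rsl(benchmark_files["rsl"])
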