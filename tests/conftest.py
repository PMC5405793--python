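import numpy as np
import pytest

from dangertrack.fixtures import default_fixture_spec, simulate
from dangertrack.windows import GenomeLayout, make_windows


@pytest.fixture
def toy_layout():
    return GenomeLayout(("chrA", "chrB"), (12000, 8000))


@pytest.fixture
def toy_grid(toy_layout):
    return make_windows(toy_layout, 5000)


@pytest.fixture(scope="session")
def reference_bundle(tmp_path_factory):
    """The default synthetic study condition, generated once per session:
    10 chromosomes x 10 windows of 5 kb, 10 planted hotspot+repeat windows,
    two SV call sets, k=50/100 mappability tracks, matching blacklist."""
    spec = default_fixture_spec(seed=0)
    out = tmp_path_factory.mktemp("bundle")
    paths = simulate(spec, out)
    return spec, paths


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
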