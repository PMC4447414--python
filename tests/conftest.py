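import numpy as np
import pytest
from hypothesis import settings

from wcbench import challenge as ch
from wcbench import toycell as tc

settings.register_profile("ci", max_examples=25, derandomize=True, deadline=None)
settings.load_profile("ci")

PACKAGE_SEED = 11


@pytest.fixture(scope="session")
def spec():
    return tc.default_spec()


@pytest.fixture(scope="session")
def wildtype(spec):
    return spec.wildtype


@pytest.fixture(scope="session")
def pkg(spec):
    """The default challenge package; shared read-only across the suite."""
    return ch.generate_challenge(spec, seed=PACKAGE_SEED)


@pytest.fixture(scope="session")
def det_mutant_bundle(spec, pkg):
    """Noise-free (deterministic-mode) bundle of the mutant strain."""
    return tc.simulate_population(
        spec, pkg.reveal_truth(), n_cells=2, mode="deterministic"
    )


@pytest.fixture(scope="session")
def pkg_dir(pkg, tmp_path_factory):
    path = tmp_path_factory.mktemp("package") / "challenge"
    pkg.save(path)
    return path


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
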