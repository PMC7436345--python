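import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from netpharm import SimConfig, gen_bundle


@pytest.fixture(scope="session")
def default_bundle():
    """One coherent synthetic input bundle shared across tests (seed 0)."""
    return gen_bundle(SimConfig(seed=0))


@pytest.fixture(scope="session")
def bundle_dir(default_bundle, tmp_path_factory):
    """The default bundle written out as pipeline input files."""
    outdir = tmp_path_factory.mktemp("bundle")
    paths = default_bundle.write(outdir)
    return paths
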