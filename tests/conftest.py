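import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from zfp import synthetic


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulated family, shared across tests."""
    return synthetic.simulate(synthetic.SimConfig(seed=7))


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    """Default simulation written to disk (FASTA/GFF3/clades/truth)."""
    out = tmp_path_factory.mktemp("sim")
    result = synthetic.simulate(synthetic.SimConfig(seed=11), out_dir=out)
    return result
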