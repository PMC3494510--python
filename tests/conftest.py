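import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from xenoscreen.synthetic_data import SimulationConfig, emit_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Small synthetic dataset with two implanted transfers (10 families)."""
    cfg = SimulationConfig(
        n_donor_taxa=4, n_recipient_taxa=4, n_close_taxa=3, n_other_taxa=3,
        n_families=10, transfer_fraction=0.2, seed=11,
    )
    outdir = tmp_path_factory.mktemp("tiny_dataset")
    paths = emit_dataset(cfg, outdir)
    return cfg, paths
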