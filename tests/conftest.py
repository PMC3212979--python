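import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from satmir import synth
from satmir.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def mouse_master():
    return synth.build_mouse_master(seed=1)


@pytest.fixture(scope="session")
def rat_master(mouse_master):
    return synth.build_rat_master(mouse_master, synth.DEFAULT_RAT_DERIVATION, seed=1)


@pytest.fixture(scope="session")
def mouse_cluster_default():
    return synth.mouse_cluster(seed=42)


@pytest.fixture(scope="session")
def rat_cluster_default():
    return synth.rat_cluster(seed=42)


@pytest.fixture(scope="session")
def mouse_report():
    """Blind end-to-end mouse run (bootstrap scaled to 100 replicates)."""
    return run_pipeline(PipelineConfig(species="mouse", seed=42,
                                       bootstrap_reps=100))


@pytest.fixture(scope="session")
def rat_report():
    return run_pipeline(PipelineConfig(species="rat", seed=42,
                                       bootstrap_reps=100))


@pytest.fixture(scope="session")
def mouse_copyset(mouse_cluster_default):
    """Scan of the default mouse cluster with its true master consensus."""
    from satmir import scan as sc

    cl = mouse_cluster_default
    return sc.scan(cl.master.sequence, cl.sequence)
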