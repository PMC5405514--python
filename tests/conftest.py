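import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from tertarch.simulate import SimConfig, simulate_family


@pytest.fixture(scope="session")
def small_family():
    """A modest simulated family exercising every event type."""
    cfg = SimConfig(
        tree="((q1:0.10,q2:0.10):0.05,(q3:0.15,q4:0.12):0.05,ref:0.02);",
        n_exons=8,
        exon_length=(60, 120),
        indel_rate=0.005,
        intron_loss_prob=0.15,
        intron_gain_rate=0.2,
        motif_loss_prob=0.08,
        n_variants=4,
        seed=7,
    )
    return simulate_family(cfg)


@pytest.fixture(scope="session")
def quiet_family():
    """Substitution-only family: no indels, no intron/motif turnover."""
    cfg = SimConfig(
        tree="(qa:0.15,qb:0.10,ref:0.02);",
        n_exons=10,
        exon_length=(60, 120),
        seed=11,
    )
    return simulate_family(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
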