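import numpy as np
import pandas as pd
import pytest

from methylarray.assay import (
    AssayConfig,
    derive_probes,
    digest,
    random_annotations,
    random_genome,
    simulate_assay,
    simulate_methylomes,
)
from methylarray.design import build_design
from methylarray.preprocess import ArraySet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_genome():
    return random_genome(np.random.default_rng(7), n_chroms=2, length=80_000)


@pytest.fixture(scope="session")
def toy_annotations(toy_genome):
    return random_annotations(toy_genome, np.random.default_rng(8))


@pytest.fixture(scope="session")
def toy_probes(toy_genome):
    cfg = AssayConfig(seed=7)
    fragments = [f for rec in toy_genome.values() for f in digest(rec)]
    return derive_probes(fragments, config=cfg)


@pytest.fixture(scope="session")
def small_experiment(toy_probes):
    """One-group, four-replicate simulated experiment with planted DMRs."""
    cfg = AssayConfig(seed=11, groups=("T",), replicates=4, dmr_fraction=0.1)
    rng = np.random.default_rng(11)
    truth = simulate_methylomes(toy_probes, cfg, rng)
    design = build_design(cfg.groups, cfg.replicates, cfg.reference)
    intensities, spikeins = simulate_assay(toy_probes, truth, cfg, design, rng)
    return cfg, truth, design, ArraySet(intensities, design), spikeins
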