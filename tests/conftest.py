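from __future__ import annotations

import numpy as np
import pytest

from umiamp.clustering import ClusterParams
from umiamp.extraction import UmiDesign
from umiamp.simulate import SimConfig, default_design, simulate_run


@pytest.fixture(scope="session")
def design() -> UmiDesign:
    """The dual-UMI design used across integration tests (18 bp NNNYR arms)."""
    return default_design()


@pytest.fixture(scope="session")
def small_design() -> UmiDesign:
    """A compact design for fast unit tests."""
    return UmiDesign(
        fwd_anchor="ACGTACGTAC",
        rev_anchor="TGCATGCATG",
        umi_length=8,
        pattern="NNNYRNNN",
        max_anchor_edits=2,
        max_pattern_mismatches=1,
        terminal_window=40,
        min_read_length=20,
        max_read_length=10_000,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_sim(design: UmiDesign, **overrides) -> SimConfig:
    defaults = dict(
        design=design,
        reference_length=200,
        n_molecules=10,
        reads_per_molecule=8,
        sub_rate=0.0,
        ins_rate=0.0,
        del_rate=0.0,
        minus_strand_fraction=0.5,
        seed=42,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture
def perfect_run(design):
    """A small error-free simulated run: (reads, truth, config)."""
    config = make_sim(design)
    reads, truth = simulate_run(config)
    return reads, truth, config
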