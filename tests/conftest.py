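"""Shared fixtures: small toy genomes and pair libraries, built once."""

from __future__ import annotations

import numpy as np
import pytest

from mtcal.simulate import (
    GenomeBundle,
    SynthConfig,
    make_toy_genome,
    simulate_pairs,
)


def small_config(seed: int = 3) -> SynthConfig:
    cfg = SynthConfig(
        seed=seed,
        n_genes=60,
        chrom_length=800_000,
        n_enhancers=10,
        n_super_enhancers=2,
        n_induced_genes=10,
    )
    cfg.pairs.n_per_library = 8_000
    cfg.libraries = [("NM", 1), ("HT", 1)]
    return cfg


@pytest.fixture(scope="session")
def bundle() -> GenomeBundle:
    return make_toy_genome(small_config(), rng=np.random.default_rng(3))


@pytest.fixture(scope="session")
def pairs_and_truth(bundle):
    cfg = small_config()
    cfg.pairs.error_rate = 0.0
    frame, truth = simulate_pairs(bundle, cfg, rng=np.random.default_rng(4))
    return frame, truth
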