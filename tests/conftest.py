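"""Shared fixtures: small synthetic genomes, gene models and cohorts.

Everything is generated at test time from fixed seeds; session scope
keeps the larger objects shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gcprofiler.simulate import (SimConfig, CNVEvent, make_gene_models,
                                 random_genome)


@pytest.fixture(scope="session")
def base_config() -> SimConfig:
    """A compact tumor/blood pair: 10 Mb over 2 chromosomes."""
    return SimConfig(seed=101, genome_length=10_000_000, purity=0.6,
                     germline_rate=50.0, somatic_rate=100.0)


@pytest.fixture(scope="session")
def genes(base_config):
    return make_gene_models(base_config, n_genes=100)


@pytest.fixture(scope="session")
def genome(base_config):
    return random_genome(base_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_windows(chrom="chr1", n=300, width=50_000, depth=30.0):
    """Uniform-depth window track for hand-built purity inputs."""
    return pd.DataFrame({
        "chrom": chrom, "start": np.arange(n) * width,
        "end": (np.arange(n) + 1) * width,
        "depth": float(depth),
    })
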