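"""Shared fixtures: reduced-size simulation configs for fast end-to-end tests."""

import pytest

from gbm_tfnet.simulate import SimConfig, GenomeSim, generate_genome


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A compact study: 2 x 120 kb chromosomes, ~28 genes on the genome."""
    return SimConfig(
        seed=3,
        n_chromosomes=2,
        chrom_length_bp=120_000,
        n_genes=200,
        n_samples_per_group={"GII": 25, "GIV": 25},
        n_distal_peaks_per_chrom=30,
        n_enhancers_per_chrom=12,
        n_tf_enhancer_sites=30,
    )


@pytest.fixture(scope="session")
def small_genome(small_config) -> GenomeSim:
    return generate_genome(small_config)
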