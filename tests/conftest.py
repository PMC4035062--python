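"""Shared fixtures: small seeded synthetic worlds generated at test time."""

import pytest

from enhancerlink.simulate import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_world():
    """A compact full world (tags, expression, sequences) with planted truth."""
    cfg = SyntheticConfig(
        chrom_sizes={"chr1": 10_000_000, "chr2": 10_000_000},
        n_genes=1500,
        n_specific_enhancers_per_type=300,
        n_shared_enhancers=300,
        n_decoy_loci=200,
        n_decoy_faire=100,
        tag_depth=400_000,
        seed=7,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def sparse_world():
    """Sparser enhancer placement so distances span the full window ladder."""
    cfg = SyntheticConfig(
        chrom_sizes={"chr1": 25_000_000, "chr2": 25_000_000},
        n_genes=2000,
        n_specific_enhancers_per_type=80,
        n_shared_enhancers=0,
        n_decoy_loci=0,
        seed=1,
    )
    return generate_dataset(cfg, with_tags=False)
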