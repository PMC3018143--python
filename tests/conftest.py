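import numpy as np
import pytest

from besmap.sim import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """A fast, fully featured simulation: 3 x 2 Mb chromosomes, two
    inversions, one translocation, a paralog model, half-rate detection."""
    return SimConfig(
        n_chromosomes=3, chrom_length=2_000_000,
        n_inversions=2, n_translocations=1,
        genes_per_chrom=50, gene_length=2_000,
        dup_fraction=0.3, loss_prob=0.1,
        n_clones=400, insert_mean=150_000, insert_sd=15_000,
        end_length=500, detect_prob=0.5, seed=11,
    )


@pytest.fixture
def null_config():
    """No rearrangements, no paralogs, every end detected."""
    return SimConfig(
        n_chromosomes=3, chrom_length=2_000_000,
        n_inversions=0, n_translocations=0,
        genes_per_chrom=0, dup_fraction=0.0, loss_prob=0.0,
        n_clones=300, insert_mean=150_000, insert_sd=10_000,
        end_length=500, detect_prob=1.0, seed=5,
    )
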