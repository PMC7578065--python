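import numpy as np
import pytest

from minibarkit import RegionCoords, SimConfig, evolve_alignment, simulate_species_tree


@pytest.fixture(scope="session")
def small_cfg():
    """Compact study conditions: 8 species, 16 specimens, 300 bp."""
    return SimConfig(
        seed=7,
        n_species=8,
        n_singletons=2,
        total_specimens=16,
        seq_length=300,
        conserved_blocks=(RegionCoords(101, 120), RegionCoords(221, 240)),
    )


@pytest.fixture(scope="session")
def small_aln(small_cfg):
    tree = simulate_species_tree(small_cfg)
    aln, truth = evolve_alignment(tree, small_cfg)
    return aln, truth


@pytest.fixture(scope="session")
def full_aln():
    """Default study conditions: 67 species / 132 specimens / 19 singletons."""
    cfg = SimConfig(seed=11)
    tree = simulate_species_tree(cfg)
    aln, truth = evolve_alignment(tree, cfg)
    return aln, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
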