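import numpy as np
import pytest

from phylorefugia import phylo_metrics as pm
from phylorefugia import synthetic_data as sd
from phylorefugia.grid_assembly import GridSpec


@pytest.fixture(scope="session")
def three_tip_tree():
    """((A:1,B:1):1,C:2):0 — all hand-computable metrics."""
    return pm.parse_newick("((A:1,B:1):1,C:2):0;")


@pytest.fixture(scope="session")
def random_trees():
    """A pool of small random trees for oracle comparisons."""
    return [
        sd.gen_tree(n, 1.0, mu, seed=s)
        for s, (n, mu) in enumerate(
            [(5, 0.0), (8, 0.3), (12, 0.0), (17, 0.5), (23, 0.2), (30, 0.6)] * 2
        )
    ]


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec(0.0, 0.0, 1.0, 1.0, resolution=0.1)


@pytest.fixture(scope="session")
def tiny_world():
    """A down-scaled synthetic world for fast end-to-end tests."""
    cfg = sd.WorldConfig(
        x_max=2.0, y_max=1.5, n_species_a=30, n_species_b=30, n_trees=5,
        k_ecoregions=6, refugium_x=0.6, refugium_y=0.6, refugium_radius=0.45,
    )
    return sd.gen_world(cfg, seed=7)


def random_community(rng, labels, size):
    return sorted(rng.choice(labels, size=size, replace=False))
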