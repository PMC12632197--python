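import numpy as np
import pytest

from scist.preprocess import GenePanel
from scist.reference import ReferencePanel
from scist.simulate import SimConfig, generate_study


@pytest.fixture(scope="session")
def tiny_sim_config() -> SimConfig:
    """A miniature study: 12 genes, 2 sections x 16 spots, 64 px patches."""
    return SimConfig(n_genes=12, n_types=4, cells_per_type=40, n_sections=2,
                     spots_per_section=16, patch_size=64, seed=7,
                     mean_cells_per_patch=6.0)


@pytest.fixture(scope="session")
def tiny_study(tiny_sim_config):
    return generate_study(tiny_sim_config)


@pytest.fixture()
def random_reference_panel():
    """A 4-type reference panel with random non-negative vectors."""
    rng = np.random.default_rng(11)
    from scist.celltypes import CELL_TYPES
    panel = GenePanel(tuple(f"g{i}" for i in range(8)))
    vectors = {ct: rng.uniform(0.0, 3.0, 8) for ct in CELL_TYPES}
    return ReferencePanel(panel, vectors)
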