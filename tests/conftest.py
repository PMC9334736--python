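import numpy as np
import pytest

from chronet.atlas import ExpressionAtlas
from chronet.simulate import ModuleSpec, SimulationConfig, simulate_atlas


@pytest.fixture(scope="session")
def zt12():
    return np.arange(0, 24, 2, dtype=float)


@pytest.fixture()
def toy_atlas():
    """2 genes x 2 organs x 4 ZT with hand-set values."""
    values = np.arange(16, dtype=float).reshape(2, 2, 4) + 1.0
    return ExpressionAtlas(
        gene_ids=["GA", "GB"],
        organ_ids=["LIVER", "HEART"],
        zt_times=np.array([0.0, 6.0, 12.0, 18.0]),
        values=values,
    )


@pytest.fixture(scope="session")
def small_study():
    """A 400-gene, 20-organ synthetic study with coupled pairs (shared)."""
    cfg = SimulationConfig(n_genes=400, n_organs=20, n_coupled_pairs=40, seed=101)
    return simulate_atlas(cfg)


@pytest.fixture(scope="session")
def module_study():
    """Synthetic study with one rhythmic and one flat planted module."""
    cfg = SimulationConfig(
        n_genes=200,
        n_organs=25,
        seed=202,
        module_plan=(
            ModuleSpec(40, 0.9, rhythmic=True, phase=6.0),
            ModuleSpec(40, 0.9, rhythmic=False),
        ),
    )
    return simulate_atlas(cfg)
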