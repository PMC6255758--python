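import numpy as np
import pytest

from kneesim.config import MaterialsConfig, coarse_preset
from kneesim.gait import generate_gait
from kneesim.geometry import build_geometry
from kneesim.materials import MaterialTIPE
from kneesim.solver import JointModel


@pytest.fixture(scope="session")
def coarse_cfg():
    """Coarse 2 mm column tessellation; quick enough for unit tests."""
    return coarse_preset()


@pytest.fixture(scope="session")
def cartilage():
    m = MaterialsConfig().cartilage
    return MaterialTIPE(
        E_p=m.E_p, E_t=m.E_t, nu_p=m.nu_p, nu_tp=m.nu_tp, G_t=m.G_t,
        permeability_k=m.permeability, e0=m.void_ratio,
    )


@pytest.fixture(scope="session")
def geom_pair(coarse_cfg):
    return build_geometry(coarse_cfg.geometry, seed=1, materials=coarse_cfg.materials)


@pytest.fixture(scope="session")
def gait_default(coarse_cfg):
    return generate_gait(coarse_cfg.gait, seed=1)


@pytest.fixture(scope="session")
def model_c(coarse_cfg, geom_pair):
    """JointModel on geometry B (modes C/D)."""
    _, geom_b = geom_pair
    return JointModel(
        geom_b, coarse_cfg.materials, coarse_cfg.solver, body_weight=700.0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
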