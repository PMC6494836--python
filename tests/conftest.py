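import numpy as np
import pytest

from biapath.pathway_model import EnzymeParams, PathwaySpec, Topology


@pytest.fixture
def single_dhpaas_spec():
    """Balanced bifunctional single-enzyme pathway with substrate feed."""
    return PathwaySpec(
        topology=Topology.SINGLE_DHPAAS_PATH,
        dhpaas=EnzymeParams(vmax=5.0, km=0.05),
        phi_aldehyde=0.5, k_cond=0.1, feed_rate=2.0)


@pytest.fixture
def mao_spec():
    """Nonsymmetrical DDC-MAO pathway with amine competition."""
    return PathwaySpec(
        topology=Topology.MAO_PATH,
        ddc=EnzymeParams(vmax=10.0, km=0.1, ki={"dopamine": 0.1}),
        mao=EnzymeParams(vmax=0.5, km=0.2, ki={"amine": 0.1, "dhpaa": 0.1}),
        k_cond=0.1, feed_rate=2.0, amine_pool=20.0)


@pytest.fixture
def condensation_only_spec():
    """No enzymatic flux: pure second-order Pictet-Spengler decay."""
    return PathwaySpec(
        topology=Topology.SINGLE_DHPAAS_PATH,
        dhpaas=EnzymeParams(vmax=0.0, km=1.0), k_cond=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
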