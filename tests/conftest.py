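import numpy as np
import pandas as pd
import pytest

from synerpath.io import PipelineConfig
from synerpath.model import SynergyAssociationModel
from synerpath.simulate import make_fixture


@pytest.fixture(scope="session")
def tiny():
    """Hand-checkable miniature study: 6 cells, 30 genes, 4 pathways, 3 pairs."""
    return make_fixture("tiny", seed=11)


@pytest.fixture(scope="session")
def strong():
    """Study with planted pathway-driven synergy (odds ratio > 3, delta 40)."""
    return make_fixture("strong_signal", seed=7)


@pytest.fixture(scope="session")
def strong_fit(strong):
    """Fitted association scans on the planted-signal study."""
    bundle, _ = strong
    model = SynergyAssociationModel(bundle, PipelineConfig())
    return model, model.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
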