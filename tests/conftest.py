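import logging

import numpy as np
import pytest

import lbasim as lb
from lbasim.models import SiteModel

logging.getLogger("lbasim").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def backbone_pair_default():
    """Paired farris/felsenstein backbones at package defaults."""
    return lb.backbone_pair()


@pytest.fixture(scope="session")
def generating_mixture():
    """The 20-component Dirichlet(0.2) profile set used across experiments."""
    return lb.make_profile_set(20, 0.2, seed=5)


@pytest.fixture(scope="session")
def het_model(generating_mixture):
    """Site-heterogeneous generating model: LG + 20 profiles + gamma(0.8)."""
    return SiteModel.mixture_model(generating_mixture, alpha=0.8)


@pytest.fixture(scope="session")
def hom_model():
    """Site-homogeneous LG+G model with the same gamma shape."""
    return SiteModel.lg_g(alpha=0.8)


@pytest.fixture(scope="session")
def candidates(backbone_pair_default):
    from lbasim.topology import CandidateSet

    farris, fels = backbone_pair_default
    return CandidateSet({"farris": farris, "felsenstein": fels})


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
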