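import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from idpcompare.ergm import ErgmModel
from idpcompare.properties import ResidueProperties
from idpcompare.psn import PSN


@pytest.fixture
def props6():
    """Six-residue property table for small enumerable ERGM problems."""
    return ResidueProperties.from_sequence("DAEFRH")


@pytest.fixture
def props40():
    from idpcompare.properties import ABETA40_WT

    return ResidueProperties.from_sequence(ABETA40_WT)


def random_psn(n_nodes, rng, density=0.3):
    """Random PSN on the backbone support."""
    a = np.zeros((n_nodes, n_nodes), dtype=bool)
    idx = np.arange(n_nodes - 1)
    a[idx, idx + 1] = a[idx + 1, idx] = True
    iu, ju = np.triu_indices(n_nodes, 2)
    on = rng.random(iu.size) < density
    a[iu[on], ju[on]] = a[ju[on], iu[on]] = True
    return PSN(a)


def enumerate_support(n_nodes):
    """All simple graphs on n nodes containing the backbone path."""
    iu, ju = np.triu_indices(n_nodes, 2)
    base = np.zeros((n_nodes, n_nodes), dtype=bool)
    idx = np.arange(n_nodes - 1)
    base[idx, idx + 1] = base[idx + 1, idx] = True
    graphs = []
    for mask in range(1 << iu.size):
        a = base.copy()
        for b in range(iu.size):
            if mask >> b & 1:
                a[iu[b], ju[b]] = a[ju[b], iu[b]] = True
        graphs.append(PSN(a))
    return graphs
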