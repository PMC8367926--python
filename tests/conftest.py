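import numpy as np
import pytest

from betascape import CommunityTable, read_newick
from betascape.simulate import SimulationParams, generate_dataset

BALANCED4 = "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture
def balanced4():
    """Four-tip balanced tree with unit branch lengths (total length 6)."""
    return read_newick(BALANCED4)


@pytest.fixture
def balanced4_newick():
    return BALANCED4


def make_community(sets, species):
    """CommunityTable from a list of python sets over a species pool."""
    species = tuple(species)
    inc = np.array([[1 if s in plot else 0 for s in species]
                    for plot in sets], dtype=np.int8)
    ids = tuple(f"p{i+1}" for i in range(len(sets)))
    return CommunityTable(ids, species, inc)


@pytest.fixture
def small_synthetic():
    """Small filtered + dispersal-limited metacommunity with ground truth."""
    params = SimulationParams(n_plots=18, n_species=90, target_richness=22)
    return generate_dataset(params, seed=11)


def star_newick(labels, length=1.0):
    return "(" + ",".join(f"{t}:{length}" for t in labels) + ");"
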