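import numpy as np
import pytest

from redking import TwoCladeDesign, make_two_clade_topology
from redking.models import CodonModelParams, N_CODONS
from redking.trees import CladeTree, LICHENIZED, NON_LICHENIZED, OUTGROUP


@pytest.fixture(scope="session")
def small_design():
    return TwoCladeDesign(
        n_lichen_tips=2, n_nonlichen_tips=2, include_outgroup=True,
        branch_length_mean=0.1, clade_rate_multiplier=1.0, seed=11,
    )


@pytest.fixture(scope="session")
def small_tree(small_design):
    return make_two_clade_topology(small_design)


@pytest.fixture(scope="session")
def uniform_codon_model():
    return CodonModelParams(kappa=2.5, codon_freqs=np.full(N_CODONS, 1.0 / N_CODONS))


@pytest.fixture
def four_taxon_tree():
    """4-tip tree with a basal trifurcation: (A, B, (C, D))."""
    #  indices: tips A=0 B=1 C=2 D=3, cherry=4, root=5
    parent = np.array([5, 5, 4, 4, 5, -1])
    blens = np.array([0.12, 0.23, 0.08, 0.31, 0.17, 0.0])
    clade_map = {"A": OUTGROUP, "B": OUTGROUP, "C": LICHENIZED, "D": NON_LICHENIZED}
    return CladeTree(parent, blens, ["A", "B", "C", "D"], clade_map)
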