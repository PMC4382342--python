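import numpy as np
import pytest

from shiftscape import synth
from shiftscape.bd_models import PieceRates
from shiftscape.synth import SyntheticScenario


@pytest.fixture(scope="session")
def yule_tree_50():
    """A 50-tip pure-birth tree (b = 0.2), taxa-stopped."""
    return synth.simulate_bd_tree(0.2, 0.0, ("taxa", 50), seed=2)


@pytest.fixture(scope="session")
def bd_tree_60():
    """A 60-tip birth-death tree (b = 0.12, d = 0.02)."""
    return synth.simulate_bd_tree(0.12, 0.02, ("taxa", 60), seed=11)


@pytest.fixture(scope="session")
def shifted_tree():
    """Tree with one planted 5x speciation increase; returns (tree, truth key)."""
    scen = SyntheticScenario(
        background=PieceRates(b=0.1, d=0.0), crown_age=35.0,
        shifts=[(7.0, PieceRates(b=0.5, d=0.0), (20, 45))],
        seed=9003, tip_range=(70, 130))
    tree, keys = synth.simulate_shifted_tree(scen)
    return tree, keys[0]


def unit_richness(tree):
    return {lab: 1 for lab in tree.labels}


def shift_recovered(tree, model, truth_key, jaccard=0.9):
    """A planted shift counts as recovered if some accepted shift sits at the
    clade's MRCA, its parent, either child, or overlaps the planted tip set
    with Jaccard >= ``jaccard`` (stem-versus-crown placement slack)."""
    truth = set(truth_key)
    tn = tree.mrca(truth_key)
    ok_nodes = {tn, int(tree.parent[tn])} | set(tree.children[tn])
    for sh in model.shifts:
        if sh.node in ok_nodes:
            return True
        inter = len(truth & set(sh.key))
        union = len(truth | set(sh.key))
        if union and inter / union >= jaccard:
            return True
    return False
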