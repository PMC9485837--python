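"""Shared fixtures: small hand-checkable trees and one default synthetic study.

The default study (seed 0) is session-scoped because several suites reuse
it: 47 species, 43-tip ultrametric Yule tree, planted 20/18/9 white/pink/red
colors with the red-group variance contrast, clustered occurrence clouds.
"""

import numpy as np
import pandas as pd
import pytest

from campion import PhyloTree, phylogenetic_pca
from campion.synthetic import SyntheticScenario, simulate_study


@pytest.fixture
def three_tip_tree():
    return PhyloTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def five_tip_tree():
    return PhyloTree.from_newick("(((A:1,B:1):1,C:2):1,(D:1.5,E:1.5):1.5);")


def random_tree(rng, n_tips, ultrametric=True):
    """Random coalescent-ish topology with random branch lengths."""
    sc = SyntheticScenario(seed=int(rng.integers(2**31)), n_species=n_tips,
                           n_tree_tips=n_tips, root_age=1.0)
    from campion.synthetic import simulate_tree
    tree = simulate_tree(sc)
    if not ultrametric:
        lens = tree.edge_length * rng.uniform(0.2, 3.0, tree.n_nodes)
        lens[tree.root] = 0.0
        tree = tree.copy(edge_length=lens)
    return tree


@pytest.fixture(scope="session")
def study():
    scenario = SyntheticScenario(seed=0)
    tree, table, occurrences, truth = simulate_study(scenario)
    return {"scenario": scenario, "tree": tree, "table": table,
            "occurrences": occurrences, "truth": truth}


@pytest.fixture(scope="session")
def study_ppca(study):
    table, tree = study["table"], study["tree"]
    X = table.encoded_matrix().loc[tree.tip_labels]
    return phylogenetic_pca(X, tree)
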