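import warnings

import numpy as np
import pytest

from phylohand.model import PhyloMetaModel
from phylohand.synthetic import SimConfig, simulate_dataset, simulate_trees
from phylohand.trees import Phylogeny

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture
def three_tip():
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def sim_world():
    """A 20-species world with a real covariate effect, shared across tests."""
    cfg = SimConfig(
        n_species=20, seed=5, covariates=("BM", "ECV", "SUBS"),
        beta_true={"intercept": 0.1, "ECV": 0.25},
    )
    tree = simulate_trees(cfg, 1)[0]
    records, traits, truth = simulate_dataset(cfg, tree)
    return cfg, tree, records, traits, truth


@pytest.fixture(scope="session")
def fitted(sim_world):
    """One fitted model on the shared world (reduced draws)."""
    cfg, tree, records, traits, truth = sim_world
    model = PhyloMetaModel.from_data(records, traits, tree, ["ECV"], "MHI")
    return model.fit(chains=2, iterations=1500, warmup=500, seed=7)


def random_tree(rng: np.random.Generator, n_tips: int, labels=None) -> Phylogeny:
    """Random coalescent-ish binary tree with positive branch lengths."""
    import dendropy

    labels = labels or [f"t{i}" for i in range(n_tips)]
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes = []
    for lbl in labels:
        nd = dendropy.Node(taxon=tns.get_taxon(lbl))
        nd.edge.length = float(rng.uniform(0.1, 1.0))
        nodes.append(nd)
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), 2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(0.1, 1.0))
        parent.add_child(a)
        parent.add_child(b)
        nodes = [n for k, n in enumerate(nodes) if k not in (int(i), int(j))]
        nodes.append(parent)
    tree.seed_node = nodes[0]
    tree.seed_node.edge.length = None
    return Phylogeny(tree)
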