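import numpy as np
import pandas as pd
import pytest

from mycolife import (GeneFamilyMatrix, LifestyleMap, Phylogeny,
                      SimulationConfig, simulate_bundle)


@pytest.fixture
def quartet_tree() -> Phylogeny:
    return Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1):0;")


@pytest.fixture
def quartet_matrix() -> GeneFamilyMatrix:
    counts = pd.DataFrame(
        {"fam1": [1, 1, 0, 0], "fam2": [2, 1, 0, 0], "fam3": [2, 2, 2, 2]},
        index=["A", "B", "C", "D"])
    return GeneFamilyMatrix(counts)


@pytest.fixture
def quartet_lifestyles() -> LifestyleMap:
    labels = pd.Series({"A": "EF", "B": "EF", "C": "SAP", "D": "SAP"},
                       name="lifestyle")
    return LifestyleMap(labels, labels.isin({"EF"}))


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Reduced problem size for cheap end-to-end checks."""
    return SimulationConfig(n_tips=20, n_families=200, n_taxa=40,
                            n_root=10, n_soil=10, n_strains=12, n_plates=6,
                            n_expr_strains=3, core_size=5, n_de_genes=20,
                            n_null_genes=40)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_bundle(small_config, seed=42)


def random_tree(rng: np.random.Generator, n_tips: int) -> Phylogeny:
    """Random binary tree with random branch lengths (test helper)."""
    import dendropy
    taxa = [f"t{i}" for i in range(n_tips)]
    tree = dendropy.Tree()
    nodes = []
    for t in taxa:
        leaf = dendropy.Node()
        nodes.append(leaf)
    ns = dendropy.TaxonNamespace(taxa)
    for leaf, t in zip(nodes, taxa):
        leaf.taxon = ns.get_taxon(t)
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        nodes = [n for n in nodes if n is not a and n is not b] + [parent]
    tree.seed_node = nodes[0]
    tree.taxon_namespace = ns
    for edge in tree.preorder_edge_iter():
        edge.length = float(rng.uniform(0.1, 2.0))
    tree.seed_node.edge.length = None
    return Phylogeny(tree)
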