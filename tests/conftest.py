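import io

import numpy as np
import pandas as pd
import pytest
import skbio

from scfa_resilience import StratifiedGeneTable


def make_table(rows, samples):
    """Build a StratifiedGeneTable from {raw_feature_id: [values...]}."""
    data = pd.DataFrame.from_dict(rows, orient="index", columns=samples).astype(float)
    return StratifiedGeneTable.from_data(data)


def random_newick(rng, n_leaves, prefix="L"):
    """Random rooted binary tree with uniform(0.05, 1) branch lengths."""
    nodes = [f"{prefix}{i}:{rng.uniform(0.05, 1.0):.6f}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.05, 1.0):.6f}")
    inner = nodes[0]
    # strip the root's own branch length: the root has no edge
    inner = inner.rsplit(":", 1)[0] if inner.startswith("(") else inner
    return inner + ";"


def brute_force_pd(newick, present, rooted=True):
    """Independent PD oracle: union of per-leaf root-path edge sets."""
    tree = skbio.TreeNode.read(io.StringIO(newick))
    paths = {}
    for tip in tree.tips():
        edges = []
        node = tip
        while node.parent is not None:
            edges.append((id(node), node.length or 0.0))
            node = node.parent
        paths[tip.name] = edges
    present = [p for p in present if p in paths]
    if not present:
        return 0.0
    if rooted:
        union = {}
        for name in present:
            union.update(dict(paths[name]))
        return sum(union.values())
    # crown: drop edges shared by *all* present leaves (the root-ward spine)
    edge_sets = [dict(paths[name]) for name in present]
    union = {}
    for es in edge_sets:
        union.update(es)
    common = set(edge_sets[0])
    for es in edge_sets[1:]:
        common &= set(es)
    return sum(v for k, v in union.items() if k not in common)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def simple_table():
    """Three samples; one gene with community total, taxon strata and an
    unclassified remainder, plus UNMAPPED."""
    return make_table(
        {
            "UNMAPPED": [100.0, 50.0, 10.0],
            "G1: acetate kinase": [60.0, 40.0, 20.0],
            "G1: acetate kinase|g__Bacteroides.s__Bacteroides_sp1": [30.0, 10.0, 5.0],
            "G1: acetate kinase|g__Prevotella.s__Prevotella_sp1": [20.0, 20.0, 10.0],
            "G1: acetate kinase|unclassified": [10.0, 10.0, 5.0],
        },
        ["s1", "s2", "s3"],
    )
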