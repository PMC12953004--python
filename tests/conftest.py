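import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

import biocrustnet as bn


def tree_from_newick(s: str) -> TreeNode:
    import io

    return TreeNode.read(io.StringIO(s), format="newick")


def make_table(counts: dict, stages: dict | None = None, cyano=()) -> bn.AbundanceTable:
    """Small hand-built AbundanceTable; counts maps sample -> count list."""
    df = pd.DataFrame(counts)
    df.index = [f"t{i + 1}" for i in range(len(df))]
    stages = stages or {s: "S1" for s in df.columns}
    sample_meta = pd.DataFrame(
        {"stage": [stages[s] for s in df.columns], "replicate": range(1, len(df.columns) + 1)},
        index=df.columns,
    )
    taxon_meta = pd.DataFrame(
        {
            "kingdom": "Bacteria",
            "phylum": "P1",
            "class": "C1",
            "order": "O1",
            "family": "F1",
            "is_cyanobacterium": [t in cyano for t in df.index],
        },
        index=df.index,
    )
    return bn.AbundanceTable(df, sample_meta, taxon_meta)


@pytest.fixture(scope="session")
def small_tree():
    return bn.simulate_tree(20, rng_seed=1)


@pytest.fixture(scope="session")
def community_fixture(small_tree):
    cfg = bn.SimulationConfig(n_taxa=20, seq_depth=3000, rng_seed=3)
    return bn.simulate_communities(small_tree, cfg)


@pytest.fixture(scope="session")
def keystone_fixture():
    return bn.plant_keystone_network(80, 4, rng_seed=0, p_within=0.6, p_between=0.01)


def rng(seed=0):
    return np.random.default_rng(seed)
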