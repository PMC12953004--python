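"""Alpha diversity of a rarefied community table.

Rarefies every sample to a common depth of 1648 reads, then prints
Shannon (natural-log) and ACE per successional stage.
"""

import biocrustnet as bn

tree = bn.simulate_tree(150, rng_seed=4)
table = bn.simulate_communities(
    tree, bn.SimulationConfig(n_taxa=150, seq_depth=10_000, rng_seed=4)
)
rarefied = bn.rarefy(table, depth=1648, rng_seed=4)
div = bn.alpha_diversity(rarefied).table

print(div.groupby("stage")[["shannon", "ace", "richness"]].mean().round(2))
# Shannon is the entropy of each sample's relative abundances; ACE corrects
# observed richness upward for taxa likely missed at this sampling depth.
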