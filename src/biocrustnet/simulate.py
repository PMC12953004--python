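"""Synthetic fixtures: phylogenies, stage-structured communities, and
compositional count tables with planted correlations or keystone topology.

The generators emulate the sampling design of a four-stage biocrust
chronosequence (bare sand -> algal -> lichen -> moss crust) with nine
replicates per stage, a tagged cyanobacterial clade, and amplicon-style
compositional counts: latent (basis) abundances are log-normal, converted
to proportions per sample, and multinomially sampled at a fixed read depth.
Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import RANKS, AbundanceTable, BiocrustError

#: Stage labels used when n_stages == 4 (the biocrust chronosequence).
BIOCRUST_STAGES = ("Bs", "Al", "Li", "Mo")

# fixed salts so each sub-generator has an independent stream per user seed
_SALT_TREE = 101
_SALT_COMMUNITY = 202
_SALT_CORRELATED = 303
_SALT_NETWORK = 404


def _rng(seed: int, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), salt]))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic community generators.

    ``selection_regime`` controls how taxa are pooled on the phylogeny:
    ``homogeneous`` draws every sample from one phylogenetically clustered
    neighbourhood (a clade-window of tips around a single anchor shared by
    all stages), ``variable`` uses a different, well-separated anchor per
    stage, and ``neutral`` samples taxa uniformly.  ``selection_strength``
    sets how sharply inclusion probability falls away from the anchor: the
    window of eligible tips shrinks exponentially with strength, from the
    whole tree at 0 towards ~1.4x the per-sample richness.
    """

    n_taxa: int = 300
    n_stages: int = 4
    n_replicates: int = 9
    seq_depth: int = 10_000
    cyano_fraction: float = 0.2
    selection_regime: str = "neutral"
    selection_strength: float = 8.0
    basis_correlations: list = field(default_factory=list)
    rng_seed: int = 0
    richness_fraction: float = 0.25  # taxa present per sample / total taxa
    fungal_fraction: float = 0.25
    stage_effect_sd: float = 0.5
    sample_noise_sd: float = 0.5
    # log-scale sd of per-sample noise on the taxon-inclusion weights, so
    # replicates draw different (but equally clustered) taxon subsets
    inclusion_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_taxa < 10:
            raise BiocrustError("n_taxa must be >= 10")
        if self.n_replicates < 3:
            raise BiocrustError("n_replicates must be >= 3")
        if not 0.0 <= self.cyano_fraction <= 1.0:
            raise BiocrustError("cyano_fraction must lie in [0, 1]")
        if self.selection_regime not in ("homogeneous", "variable", "neutral"):
            raise BiocrustError(f"unknown regime {self.selection_regime!r}")
        if self.selection_strength < 0:
            raise BiocrustError("selection_strength must be non-negative")
        for i, j, rho in self.basis_correlations:
            if abs(rho) > 1:
                raise BiocrustError(f"planted rho for ({i},{j}) outside [-1,1]")

    def stage_labels(self) -> list[str]:
        if self.n_stages == 4:
            return list(BIOCRUST_STAGES)
        return [f"S{k + 1}" for k in range(self.n_stages)]


# ---------------------------------------------------------------------------
# phylogeny


def simulate_tree(n_taxa: int, rng_seed: int = 0) -> TreeNode:
    """Simulate a rooted bifurcating tree under a pure-birth (Yule) process.

    Lineages split at unit rate; waiting times between events are
    exponential with rate k (the number of extant lineages), accumulated on
    every pendant branch.  A final waiting time is added after the last
    split so all branch lengths are strictly positive.  Tips are labelled
    ``t0001`` ... in birth order.
    """
    if n_taxa < 2:
        raise BiocrustError("a tree needs at least 2 tips")
    rng = _rng(rng_seed, _SALT_TREE)
    root = TreeNode(name="root")
    first, second = TreeNode(name="t0001", length=0.0), TreeNode(name="t0002", length=0.0)
    root.extend([first, second])
    active = [first, second]
    next_label = 3
    while len(active) < n_taxa:
        dt = rng.exponential(1.0 / len(active))
        for tip in active:
            tip.length += dt
        k = rng.integers(len(active))
        parent = active.pop(k)
        kids = [
            TreeNode(name=f"t{next_label + i - 1:04d}" if i else parent.name, length=0.0)
            for i in (0, 1)
        ]
        # the splitting lineage keeps its label on one child
        parent.name = None
        parent.extend(kids)
        active.extend(kids)
        next_label += 1
    dt = rng.exponential(1.0 / len(active))
    for tip in active:
        tip.length += dt
    return root


def cophenetic_matrix(tree: TreeNode) -> pd.DataFrame:
    """Tip-to-tip (cophenetic/patristic) distances as a labelled DataFrame."""
    dm = tree.tip_tip_distances()
    return pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)


def assign_taxonomy(
    tree: TreeNode,
    cyano_fraction: float = 0.2,
    fungal_fraction: float = 0.25,
    n_families: int = 12,
) -> pd.DataFrame:
    """Attach a synthetic lineage table to the tips of ``tree``.

    Fungi are one clade of roughly ``fungal_fraction`` of the tips;
    cyanobacteria are one clade (phylum ``Cyanobacteria``) of roughly
    ``cyano_fraction`` of the tips chosen inside the bacterial part.
    Families are contiguous blocks of tips within each kingdom, mimicking
    the family-level resolution of the source communities.
    """
    tips = [t.name for t in tree.tips()]
    n = len(tips)
    tip_pos = {name: k for k, name in enumerate(tips)}

    def best_clade(target: int, allowed: set[str]) -> list[str]:
        best, best_err = None, None
        for node in tree.non_tips():
            names = [t.name for t in node.tips()]
            if not set(names) <= allowed:
                continue
            err = abs(len(names) - target)
            if len(names) < n and (best_err is None or err < best_err):
                best, best_err = names, err
        return best or []

    fungi = set(best_clade(int(round(fungal_fraction * n)), set(tips))) if fungal_fraction > 0 else set()
    bacteria = set(tips) - fungi
    cyano = set(best_clade(int(round(cyano_fraction * n)), bacteria)) if cyano_fraction > 0 else set()

    rows = {}
    for kingdom, members in (("Bacteria", bacteria), ("Fungi", fungi)):
        ordered = sorted(members, key=tip_pos.__getitem__)
        k_fam = max(1, int(round(n_families * len(members) / max(n, 1))))
        fam_size = max(1, int(np.ceil(len(ordered) / k_fam))) if ordered else 1
        for idx, name in enumerate(ordered):
            fam = idx // fam_size + 1
            is_cyano = name in cyano
            phylum = "Cyanobacteria" if is_cyano else f"{kingdom[:3]}_phylum_{fam % 3 + 1}"
            rows[name] = {
                "kingdom": kingdom,
                "phylum": phylum,
                "class": f"{kingdom[:3]}_class_{fam % 5 + 1}",
                "order": f"{kingdom[:3]}_order_{fam}",
                "family": f"{kingdom[:3]}_family_{fam:02d}",
                "is_cyanobacterium": is_cyano,
            }
    meta = pd.DataFrame.from_dict(rows, orient="index").loc[tips]
    meta.index.name = "taxon_id"
    return meta[list(RANKS) + ["is_cyanobacterium"]]


# ---------------------------------------------------------------------------
# stage-structured communities


def simulate_communities(tree: TreeNode, config: SimulationConfig) -> AbundanceTable:
    """Simulate a stage-structured count table on a phylogeny.

    Each sample contains ``richness_fraction * n_taxa`` taxa drawn without
    replacement from its stage's taxon pool.  Under selection regimes the
    pool is a contiguous window of the tree's tip order centred on the
    anchor tip (tip-order neighbours share recent ancestry, so the window
    is a phylogenetically coherent neighbourhood); its width shrinks
    exponentially with ``selection_strength`` towards ~1.4x the per-sample
    richness, realising an inclusion probability that decays with
    phylogenetic distance from the anchor.  Basis abundances are
    log-normal with a per-taxon mean, a per-stage effect and per-sample
    noise; each sample is a multinomial draw of ``seq_depth`` reads from
    its basis proportions.
    """
    if config.seq_depth <= 0:
        raise BiocrustError("seq_depth must be positive")
    taxa = [t.name for t in tree.tips()]
    if len(taxa) < config.n_taxa:
        raise BiocrustError("tree has fewer tips than config.n_taxa")
    taxa = taxa[: config.n_taxa]
    n = len(taxa)
    rng = _rng(config.rng_seed, _SALT_COMMUNITY)

    log_mean = rng.uniform(np.log(10), np.log(1000), size=n)
    stage_fx = rng.normal(0.0, config.stage_effect_sd, size=(config.n_stages, n))

    richness = max(10, int(round(config.richness_fraction * n)))
    richness = min(richness, n)

    # pool width: whole tree at strength 0, ~1.4x richness at high strength
    pool_min = min(n, int(round(1.4 * richness)))
    pool_size = int(round(pool_min + (n - pool_min) * np.exp(-config.selection_strength / 2.0)))
    pool_size = min(max(pool_size, pool_min), n)

    stages = config.stage_labels()
    if config.selection_regime == "homogeneous":
        anchors = [int(rng.integers(n))] * config.n_stages
    elif config.selection_regime == "variable":
        # evenly spaced tip-order anchors so stage pools barely overlap
        offset = int(rng.integers(n))
        anchors = [(offset + (s * n) // config.n_stages) % n for s in range(config.n_stages)]
    else:
        anchors = [None] * config.n_stages

    def window(center: int) -> np.ndarray:
        lo = max(0, min(center - pool_size // 2, n - pool_size))
        return np.arange(lo, lo + pool_size)

    cols, meta_rows = {}, []
    for s, stage in enumerate(stages):
        pool = np.arange(n) if anchors[s] is None else window(anchors[s])
        for r in range(config.n_replicates):
            noisy = np.exp(rng.normal(0.0, config.inclusion_noise_sd, size=pool.size))
            noisy = noisy / noisy.sum()
            chosen = pool[rng.choice(pool.size, size=min(richness, pool.size), replace=False, p=noisy)]
            log_abund = (
                log_mean[chosen]
                + stage_fx[s, chosen]
                + rng.normal(0.0, config.sample_noise_sd, size=richness)
            )
            basis = np.exp(log_abund)
            p = basis / basis.sum()
            draw = rng.multinomial(config.seq_depth, p)
            col = np.zeros(n, dtype=np.int64)
            col[chosen] = draw
            sid = f"{stage}_r{r + 1}"
            cols[sid] = col
            meta_rows.append({"sample_id": sid, "stage": stage, "replicate": r + 1})

    counts = pd.DataFrame(cols, index=pd.Index(taxa, name="taxon_id"))
    sample_meta = pd.DataFrame(meta_rows).set_index("sample_id")
    taxon_meta = assign_taxonomy(tree, config.cyano_fraction, config.fungal_fraction).loc[taxa]
    return AbundanceTable(counts, sample_meta, taxon_meta)


# ---------------------------------------------------------------------------
# planted-correlation compositional counts


def nearest_psd_correlation(corr: np.ndarray, eig_floor: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD correlation matrix.

    Eigenvalues are clipped at ``eig_floor`` and the result is rescaled to
    a unit diagonal, so arbitrary planted pair lists remain usable.
    """
    sym = (corr + corr.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    vals = np.clip(vals, eig_floor, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    if np.any(d <= 0) or not np.all(np.isfinite(d)):
        raise BiocrustError("correlation matrix not repairable to PSD")
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def simulate_correlated_counts(
    config: SimulationConfig, n_samples: int | None = None
) -> tuple[AbundanceTable, pd.DataFrame]:
    """Compositional counts whose latent basis carries planted correlations.

    Basis abundances are log-normal with correlations imposed through a
    Gaussian copula on the log scale: log x = mu + L z with L the Cholesky
    factor of the (PSD-repaired) planted correlation matrix, mu ~ U[log 10,
    log 1000] per taxon and unit log-scale variance.  Samples are then
    normalised to proportions and multinomially sampled at ``seq_depth``.

    Returns the count table and the ground-truth correlation matrix (after
    PSD repair) for recovery tests.
    """
    if config.seq_depth <= 0:
        raise BiocrustError("seq_depth must be positive")
    n = config.n_taxa
    m = n_samples if n_samples is not None else config.n_stages * config.n_replicates
    rng = _rng(config.rng_seed, _SALT_CORRELATED)
    taxa = [f"t{i + 1:04d}" for i in range(n)]
    name_to_idx = {t: i for i, t in enumerate(taxa)}

    corr = np.eye(n)
    for i, j, rho in config.basis_correlations:
        ii = name_to_idx[i] if isinstance(i, str) else int(i)
        jj = name_to_idx[j] if isinstance(j, str) else int(j)
        corr[ii, jj] = corr[jj, ii] = rho
    corr = nearest_psd_correlation(corr)

    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(n))
    mu = rng.uniform(np.log(10), np.log(1000), size=n)
    z = rng.standard_normal(size=(m, n)) @ chol.T
    basis = np.exp(mu + z)
    props = basis / basis.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(config.seq_depth, p) for p in props]).T

    sample_ids = [f"s{k + 1:03d}" for k in range(m)]
    counts_df = pd.DataFrame(counts, index=pd.Index(taxa, name="taxon_id"), columns=sample_ids)
    sample_meta = pd.DataFrame(
        {"stage": ["S1"] * m, "replicate": np.arange(1, m + 1)},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    n_cyano = int(round(config.cyano_fraction * n))
    taxon_meta = pd.DataFrame(
        {
            "kingdom": "Bacteria",
            "phylum": ["Cyanobacteria"] * n_cyano + ["Bac_phylum_1"] * (n - n_cyano),
            "class": "Bac_class_1",
            "order": "Bac_order_1",
            "family": "Bac_family_01",
            "is_cyanobacterium": [True] * n_cyano + [False] * (n - n_cyano),
        },
        index=pd.Index(taxa, name="taxon_id"),
    )
    truth = pd.DataFrame(corr, index=taxa, columns=taxa)
    return AbundanceTable(counts_df, sample_meta, taxon_meta), truth


# ---------------------------------------------------------------------------
# planted keystone topology


def plant_keystone_network(
    n_nodes: int,
    n_modules: int,
    rng_seed: int = 0,
    p_within: float = 0.6,
    p_between: float = 0.01,
    n_connectors: int = 1,
    connector_coverage: float = 0.25,
) -> tuple[nx.Graph, dict]:
    """Modular random graph with designated module hubs and connectors.

    Nodes are split into ``n_modules`` near-equal modules wired as
    Erdos-Renyi blocks (``p_within`` inside, ``p_between`` between).  The
    first node of each module is a designated hub, additionally wired to
    every member of its module.  ``n_connectors`` designated connectors
    (drawn from distinct modules, never a hub) are each wired to
    ``connector_coverage`` of every module, giving them high among-module
    participation.  Returns the graph and a ground-truth dict with the
    planted partition, hubs and connectors.
    """
    if not n_nodes >= n_modules >= 2:
        raise BiocrustError("need n_nodes >= n_modules >= 2")
    if n_connectors > n_modules:
        raise BiocrustError("n_connectors cannot exceed n_modules")
    rng = _rng(rng_seed, _SALT_NETWORK)
    nodes = [f"n{k:03d}" for k in range(n_nodes)]
    module_of = {node: k % n_modules for k, node in enumerate(nodes)}
    members = {m: [node for node in nodes if module_of[node] == m] for m in range(n_modules)}

    g = nx.Graph()
    g.add_nodes_from(nodes)
    hubs = [members[m][0] for m in range(n_modules)]
    connectors = [members[m][1] for m in range(n_connectors)]

    for m, mem in members.items():
        for a in range(len(mem)):
            for b in range(a + 1, len(mem)):
                if mem[a] in hubs or mem[b] in hubs or rng.random() < p_within:
                    g.add_edge(mem[a], mem[b])
    if p_between > 0:
        for ma in range(n_modules):
            for mb in range(ma + 1, n_modules):
                for a in members[ma]:
                    for b in members[mb]:
                        if rng.random() < p_between:
                            g.add_edge(a, b)
    for c in connectors:
        for m, mem in members.items():
            k = max(1, int(np.ceil(connector_coverage * len(mem))))
            candidates = [v for v in mem if v != c]
            for v in rng.choice(candidates, size=min(k, len(candidates)), replace=False):
                g.add_edge(c, v)

    nx.set_node_attributes(g, module_of, "module_true")
    nx.set_node_attributes(g, {v: v in hubs for v in nodes}, "is_hub_true")
    nx.set_node_attributes(g, {v: v in connectors for v in nodes}, "is_connector_true")
    nx.set_node_attributes(g, "Bacteria", "kingdom")
    nx.set_node_attributes(g, False, "is_cyanobacterium")
    nx.set_edge_attributes(g, 0.8, "rho")
    nx.set_edge_attributes(g, "+", "sign")
    nx.set_edge_attributes(g, 0.001, "p")
    truth = {"module_of": module_of, "hubs": hubs, "connectors": connectors}
    return g, truth
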