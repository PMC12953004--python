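"""Co-occurrence network construction, keystone detection and stability.

Networks are undirected graphs over taxa that pass an abundance/prevalence
filter, with edges for SparCC correlations of |rho| >= 0.65 at p <= 0.05
(signs retained as attributes).  Module structure comes from greedy
modularity maximisation; node roles follow the within-module degree
z-score (Zi) and among-module participation coefficient (Pi) with the
conventional thresholds Zi = 2.5 and Pi = 0.62: connectors (Zi <= 2.5,
Pi > 0.62), module hubs (Zi > 2.5, Pi <= 0.62) and network hubs (Zi > 2.5,
Pi > 0.62) are collectively the keystone taxa.

Stability is probed two ways: robustness — the proportion of taxa
remaining after node removal plus a secondary-extinction cascade that
iteratively deletes newly isolated nodes — and vulnerability — the
largest relative drop in global efficiency caused by deleting a single
node.
"""

from __future__ import annotations

import itertools
import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    AbundanceTable,
    BiocrustError,
    CorrelationResult,
    DegenerateInputError,
    GroupComparisonResult,
    StabilityResult,
)

logger = logging.getLogger(__name__)

PERIPHERAL = "peripheral"
CONNECTOR = "connector"
MODULE_HUB = "module_hub"
NETWORK_HUB = "network_hub"
KEYSTONE_ROLES = (CONNECTOR, MODULE_HUB, NETWORK_HUB)

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


# ---------------------------------------------------------------------------
# construction


def filter_taxa(
    table: AbundanceTable,
    min_rel_abund: float = 0.001,
    min_prevalence: int = 7,
    stage=None,
) -> AbundanceTable:
    """Abundance/prevalence filter applied before network construction.

    Keeps taxa with overall relative abundance strictly above
    ``min_rel_abund`` AND non-zero counts in at least ``min_prevalence``
    replicates.  With ``stage`` given, both criteria are evaluated on that
    stage's samples only and the returned table is restricted to them.
    """
    if stage is not None:
        table = table.subset_samples(table.samples_of_stage(stage))
    rel = table.counts.sum(axis=1) / table.counts.values.sum()
    prevalence = (table.counts > 0).sum(axis=1)
    keep = table.taxa[(rel > min_rel_abund) & (prevalence >= min_prevalence)]
    if not len(keep):
        raise DegenerateInputError("no taxon passes the abundance/prevalence filter")
    logger.info("filter_taxa: %d -> %d taxa", table.n_taxa, len(keep))
    return table.subset_taxa(keep)


def build_network(
    corr: CorrelationResult,
    taxa_meta: pd.DataFrame | None = None,
    r_min: float = 0.65,
    p_max: float = 0.05,
    mean_rel_abund: pd.Series | None = None,
) -> nx.Graph:
    """Threshold a correlation result into a co-occurrence graph.

    An edge joins taxa i, j iff |rho_ij| >= ``r_min`` and p_ij <=
    ``p_max`` (both inclusive, as conventionally printed).  Isolated nodes
    are dropped.  Node attributes are taken from ``taxa_meta`` where
    available.
    """
    rho = corr.rho
    if not np.allclose(rho.values, rho.values.T):
        raise BiocrustError("correlation matrix must be symmetric")
    pval = corr.pval if corr.pval is not None else pd.DataFrame(
        0.0, index=rho.index, columns=rho.columns
    )
    g = nx.Graph()
    taxa = list(rho.index)
    for i, j in itertools.combinations(range(len(taxa)), 2):
        r = float(rho.iloc[i, j])
        p = float(pval.iloc[i, j])
        if abs(r) >= r_min and p <= p_max:
            g.add_edge(taxa[i], taxa[j], rho=r, sign="+" if r >= 0 else "-", p=p)
    if g.number_of_edges() == 0:
        raise DegenerateInputError("no edge passes the correlation thresholds")
    for node in g.nodes:
        if taxa_meta is not None and node in taxa_meta.index:
            for key in ("kingdom", "family", "is_cyanobacterium"):
                if key in taxa_meta.columns:
                    g.nodes[node][key] = taxa_meta.loc[node, key]
        if mean_rel_abund is not None and node in mean_rel_abund.index:
            g.nodes[node]["mean_rel_abund"] = float(mean_rel_abund[node])
    return g


# ---------------------------------------------------------------------------
# topology, modules, roles


def detect_modules(net: nx.Graph, rng_seed: int = 0) -> dict:
    """Non-overlapping modularity-maximising partition (deterministic).

    Greedy agglomerative (Clauset-Newman-Moore) modularity maximisation on
    an integer-relabelled copy of the graph, with nodes pre-sorted so the
    partition does not depend on string hash randomisation.  Module ids
    are assigned by each module's smallest member.  ``rng_seed`` is
    accepted for interface symmetry; the algorithm is deterministic.
    """
    nodes = sorted(net.nodes)
    to_int = {v: k for k, v in enumerate(nodes)}
    h = nx.relabel_nodes(net, to_int, copy=True)
    communities = nx.community.greedy_modularity_communities(h)
    communities = sorted((sorted(c) for c in communities), key=lambda c: c[0])
    return {nodes[v]: mid for mid, comm in enumerate(communities) for v in comm}


def topology_summary(net: nx.Graph, partition: dict | None = None) -> dict:
    """Standard whole-network descriptors.

    Returns node/edge counts, mean degree, density, average clustering
    coefficient, modularity of the detected (or given) partition and the
    fraction of positive edges.
    """
    if net.number_of_edges() == 0:
        raise DegenerateInputError("topology summary needs at least one edge")
    if partition is None:
        partition = detect_modules(net)
    comms: dict[int, set] = {}
    for node, mid in partition.items():
        comms.setdefault(mid, set()).add(node)
    signs = [d.get("sign", "+") for _, _, d in net.edges(data=True)]
    n = net.number_of_nodes()
    return {
        "nodes": n,
        "edges": net.number_of_edges(),
        "mean_degree": 2.0 * net.number_of_edges() / n,
        "density": nx.density(net),
        "clustering": nx.average_clustering(net),
        "modularity": nx.community.modularity(net, comms.values()),
        "positive_edge_fraction": signs.count("+") / len(signs),
    }


def zipi(net: nx.Graph, partition: dict) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    Zi standardises a node's within-module degree against the mean and sd
    of within-module degrees in its own module (0 when the sd is 0).
    Pi = 1 - sum_s (k_is / k_i)^2 over modules s; isolated nodes get
    Zi = Pi = 0.
    """
    if set(partition) < set(net.nodes):
        raise BiocrustError("partition must cover all nodes")
    within = {}
    per_module = {}
    for node in net.nodes:
        m = partition[node]
        k_in = sum(1 for nb in net[node] if partition[nb] == m)
        within[node] = k_in
        per_module.setdefault(m, []).append(k_in)
    stats_m = {
        m: (float(np.mean(ks)), float(np.std(ks, ddof=0))) for m, ks in per_module.items()
    }
    rows = []
    for node in net.nodes:
        k = net.degree(node)
        mean_m, sd_m = stats_m[partition[node]]
        zi = 0.0 if sd_m == 0 or k == 0 else (within[node] - mean_m) / sd_m
        if k == 0:
            pi = 0.0
        else:
            counts: dict[int, int] = {}
            for nb in net[node]:
                counts[partition[nb]] = counts.get(partition[nb], 0) + 1
            pi = 1.0 - sum((c / k) ** 2 for c in counts.values())
        rows.append({"taxon": node, "module": partition[node], "zi": zi, "pi": pi})
    return pd.DataFrame(rows).set_index("taxon")


def classify_roles(zipi_df: pd.DataFrame) -> pd.DataFrame:
    """Assign topological roles from (Zi, Pi).

    Connectors: Zi <= 2.5 and Pi > 0.62; module hubs: Zi > 2.5 and
    Pi <= 0.62; network hubs: Zi > 2.5 and Pi > 0.62; everything else is
    peripheral.  Non-peripheral nodes are the keystone taxa.
    """
    def role(zi: float, pi: float) -> str:
        if zi > ZI_THRESHOLD:
            return NETWORK_HUB if pi > PI_THRESHOLD else MODULE_HUB
        return CONNECTOR if pi > PI_THRESHOLD else PERIPHERAL

    out = zipi_df.copy()
    out["role"] = [role(z, p) for z, p in zip(out["zi"], out["pi"])]
    return out


def keystone_nodes(roles: pd.DataFrame) -> list:
    """Nodes classified in any non-peripheral role."""
    return list(roles.index[roles["role"].isin(KEYSTONE_ROLES)])


# ---------------------------------------------------------------------------
# robustness & vulnerability


def _cascade_survivors(net: nx.Graph, removed) -> set:
    """Survivors after removing ``removed`` plus the isolation cascade."""
    g = net.copy()
    g.remove_nodes_from(removed)
    while True:
        isolated = [v for v, d in g.degree() if d == 0]
        if not isolated:
            break
        g.remove_nodes_from(isolated)
    return set(g.nodes)


def robustness_random(
    net: nx.Graph,
    fraction: float = 0.5,
    n_perm: int = 100,
    rng_seed: int = 0,
    restrict_to=None,
) -> np.ndarray:
    """Robustness replicates under random node removal.

    Each permutation removes ``ceil(fraction * N)`` uniformly chosen nodes
    (``restrict_to`` limits the candidate pool, e.g. to cyanobacterial
    nodes; the count is then ``ceil(fraction * |pool|)``), applies the
    secondary-extinction cascade, and reports the proportion of the
    original nodes remaining.
    """
    if net.number_of_nodes() == 0:
        raise BiocrustError("robustness of an empty network is undefined")
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 31]))
    pool = sorted(net.nodes) if restrict_to is None else sorted(restrict_to)
    if not set(pool) <= set(net.nodes):
        raise BiocrustError("removal pool contains nodes absent from the network")
    n = net.number_of_nodes()
    k = int(np.ceil(fraction * len(pool)))
    out = np.empty(n_perm)
    for b in range(n_perm):
        removed = rng.choice(pool, size=k, replace=False)
        out[b] = len(_cascade_survivors(net, removed)) / n
    return out


def robustness_targeted(net: nx.Graph, ordered_nodes) -> list[float]:
    """Stepwise robustness curve for an ordered (targeted) removal.

    After each node in ``ordered_nodes`` is removed (with the cascade
    re-applied to the cumulative removal set), the proportion of original
    nodes remaining is recorded.  The curve is non-increasing.
    """
    ordered = list(ordered_nodes)
    if not set(ordered) <= set(net.nodes):
        raise BiocrustError("targeted removal set contains unknown nodes")
    n = net.number_of_nodes()
    curve = []
    for step in range(1, len(ordered) + 1):
        curve.append(len(_cascade_survivors(net, ordered[:step])) / n)
    return curve


def robustness(
    net: nx.Graph,
    removal: str = "random",
    fraction: float = 0.5,
    nodes=None,
    n_perm: int = 100,
    rng_seed: int = 0,
    restrict_to=None,
) -> StabilityResult:
    """Dispatch to random-removal replicates or a targeted removal curve."""
    result = StabilityResult()
    if removal == "random":
        result.robustness_samples["random"] = robustness_random(
            net, fraction=fraction, n_perm=n_perm, rng_seed=rng_seed, restrict_to=restrict_to
        )
    elif removal == "targeted":
        if nodes is None:
            raise BiocrustError("targeted removal needs an ordered node list")
        result.robustness_curve = robustness_targeted(net, nodes)
    else:
        raise BiocrustError(f"unknown removal scheme {removal!r}")
    return result


def global_efficiency(net: nx.Graph) -> float:
    """Mean inverse shortest-path length over node pairs (0 if disconnected)."""
    return nx.global_efficiency(net)


def vulnerability(net: nx.Graph) -> float:
    """Maximal relative efficiency loss from any single node deletion.

    V = max_i (E - E_-i) / E with E the global efficiency and E_-i the
    efficiency of the graph without node i.
    """
    if net.number_of_nodes() < 3:
        raise BiocrustError("vulnerability needs at least 3 nodes")
    e = global_efficiency(net)
    if e == 0:
        raise DegenerateInputError("global efficiency is zero; vulnerability undefined")
    best = -np.inf
    for node in net.nodes:
        g = net.copy()
        g.remove_node(node)
        best = max(best, (e - global_efficiency(g)) / e)
    return float(best)


# ---------------------------------------------------------------------------
# group contrast and focal subnetworks


def remove_group(net: nx.Graph, group) -> nx.Graph:
    """Copy of the network with a node group (and incident edges) deleted.

    ``group`` is either an iterable of node ids or the name of a boolean
    node attribute (e.g. ``"is_cyanobacterium"``).
    """
    members = resolve_group(net, group)
    g = net.copy()
    g.remove_nodes_from(members)
    if g.number_of_nodes() == 0:
        raise DegenerateInputError("group removal emptied the network")
    return g


def resolve_group(net: nx.Graph, group) -> set:
    if isinstance(group, str):
        return {v for v, d in net.nodes(data=True) if d.get(group)}
    return set(group) & set(net.nodes)


def compare_with_without_group(
    net: nx.Graph,
    group="is_cyanobacterium",
    fraction: float = 0.5,
    n_perm: int = 100,
    rng_seed: int = 0,
    test: str = "welch",
) -> GroupComparisonResult:
    """Stability of the network with vs without a focal taxon group.

    Both networks derive from the same construction; the 'without' network
    deletes the group's nodes and incident edges before analysis.  Each is
    probed with random removal of ``fraction`` of its nodes over
    ``n_perm`` permutations; the replicate robustness values are compared
    with a two-sided Welch t-test (or Mann-Whitney with
    ``test="mannwhitney"``).  Vulnerability is reported for both networks
    when defined.
    """
    members = resolve_group(net, group)
    if members:
        net_without = remove_group(net, members)
        rob_without = robustness_random(net_without, fraction, n_perm, rng_seed + 1)
    else:
        # group has no presence in this network: the contrast is null
        logger.warning("compare_with_without_group: group absent from network")
        net_without = net.copy()
        rob_without = robustness_random(net_without, fraction, n_perm, rng_seed)
    rob_with = robustness_random(net, fraction, n_perm, rng_seed)
    if test == "welch":
        p = float(stats.ttest_ind(rob_with, rob_without, equal_var=False).pvalue)
    elif test == "mannwhitney":
        p = float(stats.mannwhitneyu(rob_with, rob_without, alternative="two-sided").pvalue)
    else:
        raise BiocrustError(f"unknown test {test!r}")
    if np.isnan(p):  # identical constant samples
        p = 1.0

    def _vuln(g: nx.Graph) -> float | None:
        try:
            return vulnerability(g)
        except BiocrustError:
            return None

    sw = StabilityResult(robustness_samples={"random": rob_with}, vulnerability=_vuln(net))
    so = StabilityResult(
        robustness_samples={"random": rob_without}, vulnerability=_vuln(net_without)
    )
    sw.comparison_p["with_vs_without"] = p
    return GroupComparisonResult(
        stability_with=sw,
        stability_without=so,
        n_nodes_with=net.number_of_nodes(),
        n_nodes_without=net_without.number_of_nodes(),
        p_value=p,
        test=test,
    )


def extract_focal_subnetwork(net: nx.Graph, group="is_cyanobacterium") -> tuple[nx.Graph, dict]:
    """Induced subgraph on a focal group plus its first neighbours.

    The summary reports the group's share of prokaryotic (bacterial,
    including cyanobacterial) nodes, the fraction of non-group nodes
    adjacent to the group, and positive-edge fractions of group-incident
    edges split by partner kingdom (bacteria vs fungi).
    """
    members = resolve_group(net, group)
    neighbours = set()
    for v in members:
        neighbours.update(net[v])
    sub = net.subgraph(members | neighbours).copy()

    prokaryotes = {v for v, d in net.nodes(data=True) if d.get("kingdom", "Bacteria") == "Bacteria"}
    non_group = set(net.nodes) - members
    connected = neighbours - members
    by_kingdom: dict[str, list] = {}
    for v in members:
        for nb, edata in net[v].items():
            if nb in members:
                continue
            kingdom = net.nodes[nb].get("kingdom", "Bacteria")
            by_kingdom.setdefault(kingdom, []).append(edata.get("sign", "+"))
    summary = {
        "n_group_nodes": len(members),
        "n_subnetwork_nodes": sub.number_of_nodes(),
        "group_share_of_prokaryotes": (len(members & prokaryotes) / len(prokaryotes))
        if prokaryotes
        else 0.0,
        "connected_fraction": (len(connected) / len(non_group)) if non_group else 0.0,
        "positive_fraction_bacteria": (
            by_kingdom.get("Bacteria", []).count("+") / len(by_kingdom["Bacteria"])
            if by_kingdom.get("Bacteria")
            else float("nan")
        ),
        "positive_fraction_fungi": (
            by_kingdom.get("Fungi", []).count("+") / len(by_kingdom["Fungi"])
            if by_kingdom.get("Fungi")
            else float("nan")
        ),
    }
    return sub, summary
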