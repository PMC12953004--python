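"""Reading and writing the pipeline's plain-text formats.

Count tables are TSV with taxa as rows and a header row of sample ids;
taxonomy and sample metadata are TSV keyed by taxon_id / sample_id; trees
are newick; networks are written as GraphML plus Gephi-style node/edge
CSVs; ground truth and manifests are JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import AbundanceTable, BiocrustError

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# tabular formats


def write_counts_tsv(table: AbundanceTable, path) -> None:
    df = table.counts.copy()
    df.index.name = "taxon_id"
    df.to_csv(path, sep="\t")


def write_taxonomy_tsv(table: AbundanceTable, path) -> None:
    df = table.taxon_meta.copy()
    df.index.name = "taxon_id"
    df = df.assign(is_cyanobacterium=df["is_cyanobacterium"].astype(int))
    df.to_csv(path, sep="\t")


def write_metadata_tsv(table: AbundanceTable, path) -> None:
    df = table.sample_meta.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def write_table(table: AbundanceTable, outdir, prefix: str = "") -> dict:
    """Write the three TSVs of an abundance table; returns their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / f"{prefix}counts.tsv",
        "taxonomy": outdir / f"{prefix}taxonomy.tsv",
        "metadata": outdir / f"{prefix}metadata.tsv",
    }
    write_counts_tsv(table, paths["counts"])
    write_taxonomy_tsv(table, paths["taxonomy"])
    write_metadata_tsv(table, paths["metadata"])
    return paths


def read_table(counts_path, taxonomy_path, metadata_path) -> AbundanceTable:
    """Assemble an AbundanceTable from its three TSV files."""
    try:
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise BiocrustError(f"malformed count table {counts_path}: {exc}") from exc
    counts = counts.astype(np.int64)
    taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col=0)
    if "is_cyanobacterium" in taxonomy.columns:
        taxonomy["is_cyanobacterium"] = taxonomy["is_cyanobacterium"].astype(bool)
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
    return AbundanceTable(counts, metadata, taxonomy)


# ---------------------------------------------------------------------------
# trees


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_tree(path) -> TreeNode:
    try:
        return TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise BiocrustError(f"malformed newick file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# networks


def _native(value):
    if isinstance(value, (np.bool_,)):
        return bool(value)
    if isinstance(value, np.integer):
        return int(value)
    if isinstance(value, np.floating):
        return float(value)
    return value


def sanitize_graph(net: nx.Graph) -> nx.Graph:
    """Copy with numpy scalar attributes converted to Python natives."""
    g = net.copy()
    for _, data in g.nodes(data=True):
        for k in list(data):
            data[k] = _native(data[k])
    for _, _, data in g.edges(data=True):
        for k in list(data):
            data[k] = _native(data[k])
    return g


def write_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(sanitize_graph(net), str(path))


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(str(path))


def write_gephi_csvs(net: nx.Graph, nodes_path, edges_path) -> None:
    """Gephi-compatible node and edge lists."""
    nodes = pd.DataFrame(
        [{"Id": v, "Label": v, **{k: _native(x) for k, x in d.items()}} for v, d in net.nodes(data=True)]
    )
    edges = pd.DataFrame(
        [
            {"Source": a, "Target": b, "Type": "Undirected", **{k: _native(x) for k, x in d.items()}}
            for a, b, d in net.edges(data=True)
        ]
    )
    nodes.to_csv(nodes_path, index=False, float_format=_FLOAT_FMT)
    edges.to_csv(edges_path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# JSON helpers


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.ndarray,)):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# cross-referenced input loading


def read_inputs(
    counts_path, taxonomy_path, metadata_path, tree_path=None, strict: bool = True
) -> tuple[AbundanceTable, TreeNode | None]:
    """Load and cross-reference the pipeline inputs.

    Taxa present in the table but absent from the taxonomy or the tree are
    an error in strict mode; in lenient mode they are dropped with a
    warning.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0).astype(np.int64)
    taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col=0)
    if "is_cyanobacterium" in taxonomy.columns:
        taxonomy["is_cyanobacterium"] = taxonomy["is_cyanobacterium"].astype(bool)
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
    tree = read_tree(tree_path) if tree_path else None

    known = set(taxonomy.index)
    if tree is not None:
        known &= {t.name for t in tree.tips()}
    missing = [t for t in counts.index if t not in known]
    if missing:
        if strict:
            raise BiocrustError(
                f"{len(missing)} table taxa missing from taxonomy/tree, e.g. {missing[:5]}"
            )
        logger.warning("dropping %d taxa missing from taxonomy/tree", len(missing))
        counts = counts.drop(index=missing)
    table = AbundanceTable(counts, metadata, taxonomy.loc[counts.index])
    return table, tree


def float_format() -> str:
    return _FLOAT_FMT
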