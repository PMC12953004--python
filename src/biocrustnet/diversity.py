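"""Alpha diversity, rarefaction, dissimilarity and taxon aggregation.

Shannon entropy uses natural logarithms.  ACE follows the classical
abundance-based coverage estimator with a rare-taxon threshold of 10
individuals; when every rare taxon is a singleton (sample coverage zero)
the estimate falls back to bias-corrected Chao1 with a warning.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .containers import AbundanceTable, BiocrustError, DegenerateInputError, DiversityResult, RANKS

logger = logging.getLogger(__name__)


def rarefy(table: AbundanceTable, depth: int, rng_seed: int = 0) -> AbundanceTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples whose total is below ``depth`` are dropped with a warning.  The
    draw is multivariate hypergeometric, i.e. equivalent to drawing
    ``depth`` reads from the sample's read pool without replacement.
    """
    if depth < 1:
        raise BiocrustError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 77]))
    totals = table.counts.sum(axis=0)
    keep = totals.index[totals >= depth]
    dropped = totals.index.difference(keep)
    if len(dropped):
        logger.warning(
            "rarefy: dropping %d sample(s) below depth %d: %s",
            len(dropped), depth, list(dropped),
        )
    if not len(keep):
        raise DegenerateInputError(f"no sample reaches rarefaction depth {depth}")
    cols = {}
    for sid in keep:
        col = table.counts[sid].to_numpy()
        if col.sum() == depth:
            cols[sid] = col.copy()
        else:
            cols[sid] = rng.multivariate_hypergeometric(col, depth)
    counts = pd.DataFrame(cols, index=table.counts.index)
    return AbundanceTable(counts, table.sample_meta.loc[keep].copy(), table.taxon_meta.copy())


def shannon(counts_vector) -> float:
    """Shannon diversity H = -sum p_i ln p_i over positive-count taxa."""
    x = np.asarray(counts_vector, dtype=float)
    x = x[x > 0]
    if x.size == 0:
        raise BiocrustError("Shannon index undefined for an all-zero sample")
    p = x / x.sum()
    return float(-(p * np.log(p)).sum())


def ace(counts_vector, rare_threshold: int = 10) -> float:
    """Abundance-based coverage estimator of richness.

    Taxa with count <= ``rare_threshold`` form the rare group.  With
    S_abund the abundant richness, S_rare the rare richness, N_rare the
    rare reads, F1 the singletons and C = 1 - F1/N_rare the sample
    coverage::

        ACE = S_abund + S_rare/C + (F1/C) * gamma^2

    where gamma^2 = max(S_rare/C * sum i(i-1)F_i / (N_rare(N_rare-1)) - 1, 0).
    If every rare taxon is a singleton (C = 0) the estimator is undefined
    and bias-corrected Chao1 is returned instead.
    """
    x = np.asarray(counts_vector, dtype=float)
    x = x[x > 0]
    if x.size == 0:
        raise BiocrustError("ACE undefined for an all-zero sample")
    rare = x[x <= rare_threshold]
    s_abund = int((x > rare_threshold).sum())
    s_rare = rare.size
    if s_rare == 0:
        return float(s_abund)
    n_rare = rare.sum()
    f1 = int((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        logger.warning("ace: all rare taxa are singletons; falling back to Chao1")
        return _chao1(x)
    fi = np.array([(rare == i).sum() for i in range(1, rare_threshold + 1)])
    i_arr = np.arange(1, rare_threshold + 1)
    gamma2 = (s_rare / c_ace) * (i_arr * (i_arr - 1) * fi).sum() / (n_rare * (n_rare - 1.0)) - 1.0
    gamma2 = max(gamma2, 0.0)
    return float(s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2)


def _chao1(x: np.ndarray) -> float:
    """Bias-corrected Chao1: S + F1(F1-1) / (2 (F2+1))."""
    s_obs = x.size
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def alpha_diversity(table: AbundanceTable, rare_threshold: int = 10) -> DiversityResult:
    """Per-sample Shannon, ACE and observed richness as a tidy frame."""
    rows = []
    for sid in table.samples:
        col = table.counts[sid].to_numpy()
        rows.append(
            {
                "sample_id": sid,
                "stage": table.sample_meta.loc[sid, "stage"],
                "shannon": shannon(col),
                "ace": ace(col, rare_threshold),
                "richness": int((col > 0).sum()),
            }
        )
    return DiversityResult(pd.DataFrame(rows))


def bray_curtis(table: AbundanceTable) -> pd.DataFrame:
    """Sample x sample Bray-Curtis dissimilarity matrix."""
    if table.n_samples < 2:
        raise BiocrustError("Bray-Curtis needs at least 2 samples")
    mat = squareform(pdist(table.counts.T.to_numpy(dtype=float), metric="braycurtis"))
    return pd.DataFrame(mat, index=table.samples, columns=table.samples)


def shared_unique_partition(table: AbundanceTable, group_by: str = "stage") -> dict:
    """Partition taxa by their presence pattern across sample groups.

    Every taxon with any reads falls into exactly one of the 2^k - 1
    non-empty presence cells (k groups).  Each cell reports its taxon set
    and, per group, the pooled relative abundance those taxa represent, so
    sibling cells of a group sum to 1.
    """
    groups = list(dict.fromkeys(table.sample_meta[group_by]))
    if len(groups) < 2:
        raise BiocrustError("shared/unique partition needs >= 2 groups")
    pooled = pd.DataFrame(
        {g: table.counts[table.sample_meta.index[table.sample_meta[group_by] == g]].sum(axis=1)
         for g in groups}
    )
    group_totals = pooled.sum(axis=0)
    out: dict[str, dict] = {}
    present = pooled > 0
    for taxon in pooled.index[present.any(axis=1)]:
        label = "&".join(g for g in groups if present.loc[taxon, g])
        cell = out.setdefault(label, {"taxa": set(), "rel_abundance": {g: 0.0 for g in groups}})
        cell["taxa"].add(taxon)
        for g in groups:
            if group_totals[g] > 0:
                cell["rel_abundance"][g] += pooled.loc[taxon, g] / group_totals[g]
    return out


def aggregate_by_rank(table: AbundanceTable, rank: str) -> AbundanceTable:
    """Sum counts over taxa sharing a lineage rank value.

    Lineages lacking an assignment at ``rank`` are pooled under
    ``unclassified <nearest classified ancestor>``.
    """
    if rank not in table.taxon_meta.columns or rank not in RANKS:
        raise BiocrustError(f"unknown rank {rank!r}")
    ranks_up = list(RANKS[: RANKS.index(rank) + 1])

    def label(taxon) -> str:
        val = table.taxon_meta.loc[taxon, rank]
        if isinstance(val, str) and val:
            return val
        for r in reversed(ranks_up[:-1]):
            parent = table.taxon_meta.loc[taxon, r]
            if isinstance(parent, str) and parent:
                return f"unclassified {parent}"
        return "unclassified"

    labels = pd.Series({t: label(t) for t in table.taxa}, name=rank)
    counts = table.counts.groupby(labels).sum()
    counts.index.name = "taxon_id"
    meta_rows = {}
    for name in counts.index:
        members = labels.index[labels == name]
        sub = table.taxon_meta.loc[members]
        row = {r: (sub[r].iloc[0] if sub[r].nunique() == 1 else "") for r in RANKS}
        row[rank] = name
        row["is_cyanobacterium"] = bool(sub["is_cyanobacterium"].any())
        meta_rows[name] = row
    taxon_meta = pd.DataFrame.from_dict(meta_rows, orient="index").loc[counts.index]
    taxon_meta.index.name = "taxon_id"
    return AbundanceTable(counts, table.sample_meta.copy(), taxon_meta)
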