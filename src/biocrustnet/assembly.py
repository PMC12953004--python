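"""Null-model phylogenetic beta-diversity: betaMNTD, betaNTI and the
classification of community-assembly processes.

The framework compares the observed between-community mean nearest-taxon
distance (betaMNTD, abundance weighted) with a null distribution obtained
by shuffling taxon labels across the tips of the phylogeny (richness and
abundances preserved, phylogenetic relationships randomised).  The
standardised effect size betaNTI = (obs - mean_null) / sd_null is read
against fixed thresholds: below -2 indicates homogeneous selection
(communities more phylogenetically similar than expected), above +2
variable selection, and |betaNTI| < 2 a stochastic outcome.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import AbundanceTable, AssemblyResult, BiocrustError
from .simulate import cophenetic_matrix

logger = logging.getLogger(__name__)

HOMOGENEOUS = "homogeneous_selection"
VARIABLE = "variable_selection"
STOCHASTIC = "stochastic"
UNCLASSIFIED = "unclassified"
PROCESSES = (HOMOGENEOUS, VARIABLE, STOCHASTIC)

#: betaNTI magnitude separating selection from stochasticity.
BNTI_THRESHOLD = 2.0


def cophenetic_distances(tree: TreeNode) -> pd.DataFrame:
    """Tip-to-tip patristic distance matrix of a tree with branch lengths."""
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise BiocrustError("tree has missing branch lengths")
    return cophenetic_matrix(tree)


def beta_mntd(comm_a, comm_b, dist: np.ndarray, weighted: bool = True) -> float:
    """Abundance-weighted mean nearest-taxon distance between two communities.

    ``comm_a`` and ``comm_b`` are count vectors aligned to the rows of
    ``dist``.  For each taxon in one community the distance to its nearest
    taxon in the other community is taken (0 for shared taxa), weighted by
    relative abundance, and the two directions are averaged.
    """
    a = np.asarray(comm_a, dtype=float)
    b = np.asarray(comm_b, dtype=float)
    ia = np.flatnonzero(a > 0)
    ib = np.flatnonzero(b > 0)
    if ia.size == 0 or ib.size == 0:
        raise BiocrustError("betaMNTD requires two non-empty communities")
    if weighted:
        fa = a[ia] / a[ia].sum()
        fb = b[ib] / b[ib].sum()
    else:
        fa = np.full(ia.size, 1.0 / ia.size)
        fb = np.full(ib.size, 1.0 / ib.size)
    sub = dist[np.ix_(ia, ib)]
    return float(0.5 * (fa @ sub.min(axis=1) + fb @ sub.min(axis=0)))


def _null_bmntd(
    ia: np.ndarray,
    ib: np.ndarray,
    fa: np.ndarray,
    fb: np.ndarray,
    dist: np.ndarray,
    perms: np.ndarray,
) -> np.ndarray:
    """betaMNTD under each tip-label permutation in ``perms`` (rows)."""
    out = np.empty(len(perms))
    for k, perm in enumerate(perms):
        sub = dist[np.ix_(perm[ia], perm[ib])]
        out[k] = 0.5 * (fa @ sub.min(axis=1) + fb @ sub.min(axis=0))
    return out


def beta_nti(
    comm_a,
    comm_b,
    dist: np.ndarray,
    n_null: int = 999,
    rng_seed: int | None = 0,
    weighted: bool = True,
    exhaustive: bool = False,
) -> float:
    """Standardised effect size of betaMNTD against a tip-shuffling null.

    The null randomises the assignment of taxa to tips across the full
    taxon pool of the distance matrix.  With ``exhaustive=True`` all
    permutations are enumerated instead of sampled (only sensible for a
    handful of taxa); otherwise ``n_null`` draws are taken.  Returns NaN
    with a warning when the null has zero spread.
    """
    if not exhaustive and n_null < 99:
        raise BiocrustError("n_null must be >= 99")
    a = np.asarray(comm_a, dtype=float)
    b = np.asarray(comm_b, dtype=float)
    obs = beta_mntd(a, b, dist, weighted=weighted)
    mean_null, sd_null = null_bmntd_moments(
        a, b, dist, n_null=n_null, rng_seed=rng_seed, weighted=weighted, exhaustive=exhaustive
    )
    if sd_null == 0:
        logger.warning("beta_nti: null distribution has zero spread; returning NaN")
        return float("nan")
    return float((obs - mean_null) / sd_null)


def null_bmntd_moments(
    comm_a,
    comm_b,
    dist: np.ndarray,
    n_null: int = 999,
    rng_seed: int | None = 0,
    weighted: bool = True,
    exhaustive: bool = False,
) -> tuple[float, float]:
    """Mean and (population) sd of betaMNTD over the tip-label null."""
    a = np.asarray(comm_a, dtype=float)
    b = np.asarray(comm_b, dtype=float)
    n = dist.shape[0]
    ia = np.flatnonzero(a > 0)
    ib = np.flatnonzero(b > 0)
    if weighted:
        fa = a[ia] / a[ia].sum()
        fb = b[ib] / b[ib].sum()
    else:
        fa = np.full(ia.size, 1.0 / ia.size)
        fb = np.full(ib.size, 1.0 / ib.size)
    if exhaustive:
        if n > 8:
            raise BiocrustError("exhaustive null only supported for <= 8 taxa")
        perms = np.array(list(itertools.permutations(range(n))))
    else:
        rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed or 0), 55]))
        perms = np.array([rng.permutation(n) for _ in range(n_null)])
    nulls = _null_bmntd(ia, ib, fa, fb, dist, perms)
    return float(nulls.mean()), float(nulls.std(ddof=0 if exhaustive else 1))


def classify_assembly(bnti_value: float) -> str:
    """Map a betaNTI value to its assembly-process label (strict +/-2)."""
    if math.isnan(bnti_value):
        logger.warning("classify_assembly: NaN betaNTI left unclassified")
        return UNCLASSIFIED
    if bnti_value < -BNTI_THRESHOLD:
        return HOMOGENEOUS
    if bnti_value > BNTI_THRESHOLD:
        return VARIABLE
    return STOCHASTIC


def stage_fractions(
    table: AbundanceTable,
    tree: TreeNode,
    n_null: int = 999,
    rng_seed: int = 0,
    within_stage: bool = True,
    exclude_cyanobacteria: bool = False,
) -> AssemblyResult:
    """betaNTI over sample pairs and per-stage assembly-process fractions.

    By default only within-stage pairs are evaluated (C(r,2) per stage);
    ``within_stage=False`` evaluates all pairs and attributes each pair to
    the ordered stage pair instead.  Stages with fewer than two samples
    are skipped with a warning.  ``exclude_cyanobacteria`` removes flagged
    taxa before the analysis.
    """
    if exclude_cyanobacteria:
        keep = table.taxa[~table.taxon_meta["is_cyanobacterium"].astype(bool)]
        table = table.subset_taxa(keep).drop_empty_taxa()
    dist_df = cophenetic_distances(tree)
    missing = table.taxa.difference(dist_df.index)
    if len(missing):
        raise BiocrustError(f"taxa absent from tree: {list(missing)[:5]}")
    dist = dist_df.loc[table.taxa, table.taxa].to_numpy()
    counts = table.counts.to_numpy(dtype=float)
    sample_pos = {s: k for k, s in enumerate(table.samples)}
    stage_of = table.sample_meta["stage"]

    if within_stage:
        pairs = []
        for stage in table.stages():
            sids = list(table.samples_of_stage(stage))
            if len(sids) < 2:
                logger.warning("stage %r has < 2 samples; skipped", stage)
                continue
            pairs.extend(itertools.combinations(sids, 2))
    else:
        pairs = list(itertools.combinations(list(table.samples), 2))

    ss = np.random.SeedSequence([int(rng_seed), 56]).spawn(len(pairs))
    rows = []
    for (sa, sb), seed in zip(pairs, ss):
        ca = counts[:, sample_pos[sa]]
        cb = counts[:, sample_pos[sb]]
        obs = beta_mntd(ca, cb, dist)
        z = beta_nti(ca, cb, dist, n_null=n_null, rng_seed=int(seed.generate_state(1)[0] % (2**31)))
        rows.append(
            {
                "sample_a": sa,
                "sample_b": sb,
                "stage_a": stage_of[sa],
                "stage_b": stage_of[sb],
                "bmntd_obs": obs,
                "bnti": z,
                "process": classify_assembly(z),
            }
        )
    pair_df = pd.DataFrame(rows)

    frac_rows = {}
    for stage in table.stages():
        sub = pair_df[(pair_df["stage_a"] == stage) & (pair_df["stage_b"] == stage)]
        if not len(sub):
            continue
        frac_rows[stage] = {p: float((sub["process"] == p).mean()) for p in PROCESSES}
    frac_df = pd.DataFrame.from_dict(frac_rows, orient="index")
    frac_df.index.name = "stage"
    return AssemblyResult(pairs=pair_df, stage_fractions=frac_df, n_null=n_null)
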