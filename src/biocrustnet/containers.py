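"""Core data containers shared across the pipeline.

The central object is :class:`AbundanceTable`, a taxon-by-sample matrix of
non-negative integer counts with sample metadata (successional stage,
replicate) and taxon metadata (taxonomic lineage, cyanobacterial flag).
Result containers for the assembly, correlation and stability analyses
live here too so that downstream modules only exchange typed bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Lineage ranks carried by taxon metadata, from coarsest to finest.
RANKS = ("kingdom", "phylum", "class", "order", "family")


class BiocrustError(ValueError):
    """Base class for domain errors raised by this package."""


class DegenerateInputError(BiocrustError):
    """An operation produced or received an empty/degenerate result."""


@dataclass
class AbundanceTable:
    """Taxon x sample count matrix with sample and taxon metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers; rows are taxa, columns samples.
    sample_meta
        DataFrame indexed by sample id with at least columns ``stage`` and
        ``replicate``; must cover every column of ``counts``.
    taxon_meta
        DataFrame indexed by taxon id with lineage ranks and a boolean
        ``is_cyanobacterium`` column; must cover every row of ``counts``.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    taxon_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise BiocrustError("count matrix contains negative entries")
        if self.counts.index.has_duplicates:
            raise BiocrustError("duplicate taxon ids")
        if self.counts.columns.has_duplicates:
            raise BiocrustError("duplicate sample ids")
        missing = self.counts.columns.difference(self.sample_meta.index)
        if len(missing):
            raise BiocrustError(f"samples missing from metadata: {list(missing)[:5]}")
        if "stage" not in self.sample_meta.columns:
            raise BiocrustError("sample metadata lacks a 'stage' column")
        missing_t = self.counts.index.difference(self.taxon_meta.index)
        if len(missing_t):
            raise BiocrustError(f"taxa missing from taxonomy: {list(missing_t)[:5]}")
        # align metadata to the matrix order
        self.sample_meta = self.sample_meta.loc[self.counts.columns]
        self.taxon_meta = self.taxon_meta.loc[self.counts.index]

    # -- convenience accessors -------------------------------------------------

    @property
    def taxa(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def stages(self) -> list:
        """Stage labels in first-appearance order."""
        return list(dict.fromkeys(self.sample_meta["stage"]))

    def samples_of_stage(self, stage) -> pd.Index:
        mask = self.sample_meta["stage"] == stage
        return self.sample_meta.index[mask]

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1)."""
        totals = self.counts.sum(axis=0)
        return self.counts / totals.replace(0, np.nan)

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        ids = pd.Index(sample_ids)
        return AbundanceTable(
            self.counts[ids].copy(),
            self.sample_meta.loc[ids].copy(),
            self.taxon_meta.copy(),
        )

    def subset_taxa(self, taxon_ids) -> "AbundanceTable":
        ids = pd.Index(taxon_ids)
        return AbundanceTable(
            self.counts.loc[ids].copy(),
            self.sample_meta.copy(),
            self.taxon_meta.loc[ids].copy(),
        )

    def drop_empty_taxa(self) -> "AbundanceTable":
        keep = self.counts.sum(axis=1) > 0
        return self.subset_taxa(self.counts.index[keep])


@dataclass
class DiversityResult:
    """Per-sample alpha diversity: Shannon (natural log), ACE, richness."""

    table: pd.DataFrame  # columns: sample_id, stage, shannon, ace, richness


@dataclass
class AssemblyResult:
    """Pairwise betaNTI values and the per-stage process fractions.

    ``pairs`` has one row per evaluated sample pair with columns
    ``sample_a, sample_b, stage_a, stage_b, bmntd_obs, bnti, process``.
    ``stage_fractions`` is indexed by stage with columns
    ``homogeneous_selection, variable_selection, stochastic`` summing to 1.
    """

    pairs: pd.DataFrame
    stage_fractions: pd.DataFrame
    n_null: int


@dataclass
class CorrelationResult:
    """SparCC correlation estimates with permutation pseudo p-values."""

    rho: pd.DataFrame
    pval: pd.DataFrame | None = None
    n_boot: int = 0
    excluded_pairs: set = field(default_factory=set)

    def edge_candidates(self) -> pd.DataFrame:
        """Long-format upper-triangle listing (taxon_i, taxon_j, rho, p)."""
        taxa = self.rho.index
        rows = []
        r = self.rho.values
        p = self.pval.values if self.pval is not None else None
        for i in range(len(taxa)):
            for j in range(i + 1, len(taxa)):
                rows.append(
                    {
                        "taxon_i": taxa[i],
                        "taxon_j": taxa[j],
                        "rho": r[i, j],
                        "p": p[i, j] if p is not None else np.nan,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class StabilityResult:
    """Robustness and vulnerability of one network under removal schemes.

    ``robustness_samples`` maps a scheme label to the per-permutation
    proportions of taxa remaining; ``robustness_curve`` holds the stepwise
    remaining proportions of a targeted (ordered) removal, if computed.
    """

    robustness_samples: dict = field(default_factory=dict)
    robustness_curve: list | None = None
    vulnerability: float | None = None
    comparison_p: dict = field(default_factory=dict)


@dataclass
class GroupComparisonResult:
    """Paired stability of networks with vs without a focal taxon group."""

    stability_with: StabilityResult
    stability_without: StabilityResult
    n_nodes_with: int
    n_nodes_without: int
    p_value: float
    test: str
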