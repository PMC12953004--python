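"""SparCC: correlation inference for compositional count data.

Sequencing counts only carry relative information, so Pearson correlations
of proportions are badly biased.  SparCC works from the log-ratio variances
t_ij = Var log(x_i/x_j), which are invariant to per-sample total
rescaling.  Writing omega_i^2 for the variance of the latent (basis) log
abundance of taxon i and rho_ij for the basis correlations,

    t_ij = omega_i^2 + omega_j^2 - 2 rho_ij omega_i omega_j.

Under the sparsity assumption (most rho_ij ~ 0) the row sums of t give a
linear system for the omega^2, and the correlations follow as

    rho_ij = (omega_i^2 + omega_j^2 - t_ij) / (2 omega_i omega_j),

clipped to [-1, 1].  Strongly correlated pairs violate the sparsity
assumption, so the strongest pair above a threshold is iteratively
excluded from the basis system and the system re-solved.  Significance is
assessed by a permutation bootstrap that destroys all correlation while
preserving each taxon's marginal distribution.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import AbundanceTable, BiocrustError, CorrelationResult, DegenerateInputError

logger = logging.getLogger(__name__)

#: Common pseudo-depth samples are rescaled to before pseudocounting, so
#: estimates depend on sample compositions only, never on library sizes.
DEFAULT_PSEUDO_DEPTH = 10_000
_OMEGA_FLOOR = 1e-10


def _as_matrix(counts) -> tuple[np.ndarray, list]:
    if isinstance(counts, AbundanceTable):
        return counts.counts.to_numpy(dtype=float), list(counts.taxa)
    if isinstance(counts, pd.DataFrame):
        return counts.to_numpy(dtype=float), list(counts.index)
    arr = np.asarray(counts, dtype=float)
    return arr, list(range(arr.shape[0]))


def pseudocount_proportions(
    counts: np.ndarray, pseudocount: float = 1.0, pseudo_depth: int = DEFAULT_PSEUDO_DEPTH
) -> np.ndarray:
    """Strictly positive per-sample proportions from a count matrix.

    Each sample (column) is rescaled to a common pseudo-depth, offset by
    ``pseudocount``, and renormalised.  Because the rescaling happens
    first, multiplying any sample's counts by a positive constant leaves
    the result exactly unchanged.
    """
    totals = counts.sum(axis=0)
    if np.any(totals <= 0):
        raise BiocrustError("every sample needs a positive total count")
    scaled = counts / totals * pseudo_depth + pseudocount
    return scaled / scaled.sum(axis=0)


def log_ratio_variances(counts, pseudocount: float = 1.0) -> np.ndarray:
    """Matrix of per-pair log-ratio variances t_ij = Var log(x_i/x_j).

    Computed from pseudocounted proportions; symmetric, zero diagonal,
    non-negative.  Requires at least 4 samples for a meaningful variance.
    """
    mat, _ = _as_matrix(counts)
    if mat.shape[1] < 4:
        raise BiocrustError("log-ratio variances need >= 4 samples")
    logp = np.log(pseudocount_proportions(mat, pseudocount))
    cov = np.cov(logp, ddof=1)
    v = np.diag(cov)
    t = v[:, None] + v[None, :] - 2.0 * cov
    np.fill_diagonal(t, 0.0)
    return np.clip(t, 0.0, None)


def estimate_basis_variances(t: np.ndarray, include: np.ndarray | None = None) -> np.ndarray:
    """Solve the sparsity-assumption linear system for basis variances.

    ``include`` is an optional boolean taxon x taxon mask of pairs kept in
    the system (excluded pairs are dropped from both the coefficient
    matrix and the row sums).  Negative solutions are floored at a small
    positive epsilon with a warning.
    """
    d = t.shape[0]
    if d < 4:
        raise BiocrustError("SparCC needs at least 4 taxa")
    if include is None:
        include = ~np.eye(d, dtype=bool)
    m = include.astype(float)
    m = m + np.diag(include.sum(axis=1))
    rhs = (t * include).sum(axis=1)
    try:
        omega2 = np.linalg.solve(m, rhs)
    except np.linalg.LinAlgError:
        logger.warning("estimate_basis_variances: singular system; using least squares")
        omega2 = np.linalg.lstsq(m, rhs, rcond=None)[0]
    if np.any(omega2 <= 0):
        logger.warning(
            "estimate_basis_variances: %d non-positive basis variance(s) floored",
            int((omega2 <= 0).sum()),
        )
        omega2 = np.clip(omega2, _OMEGA_FLOOR, None)
    return omega2


def _rho_from(t: np.ndarray, omega2: np.ndarray) -> np.ndarray:
    omega = np.sqrt(omega2)
    rho = (omega2[:, None] + omega2[None, :] - t) / (2.0 * np.outer(omega, omega))
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return (rho + rho.T) / 2.0


def sparcc_correlations(
    counts,
    n_exclusion_iter: int = 10,
    exclusion_threshold: float = 0.1,
    pseudocount: float = 1.0,
) -> CorrelationResult:
    """SparCC basis correlations with iterative strong-pair exclusion.

    After the initial solve, the single strongest-|rho| pair above
    ``exclusion_threshold`` is removed from the basis system and the
    system re-solved, up to ``n_exclusion_iter`` rounds (the original
    SparCC heuristic).  Excluded pairs keep their final rho estimate but
    no longer bias the variance solve.
    """
    mat, taxa = _as_matrix(counts)
    d = len(taxa)
    t = log_ratio_variances(mat, pseudocount)
    include = ~np.eye(d, dtype=bool)
    excluded: set[tuple] = set()
    rho = _rho_from(t, estimate_basis_variances(t, include))
    for _ in range(n_exclusion_iter):
        masked = np.where(include, np.abs(rho), 0.0)
        np.fill_diagonal(masked, 0.0)
        # keep every taxon in the system with >= 2 included partners
        excludable = include.sum(axis=1) > 2
        masked[~excludable, :] = 0.0
        masked[:, ~excludable] = 0.0
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        include[i, j] = include[j, i] = False
        excluded.add((taxa[min(i, j)], taxa[max(i, j)]))
        if not include.any():
            raise DegenerateInputError("all taxon pairs excluded from the basis system")
        rho = _rho_from(t, estimate_basis_variances(t, include))
    rho_df = pd.DataFrame(rho, index=taxa, columns=taxa)
    return CorrelationResult(rho=rho_df, excluded_pairs=excluded)


def bootstrap_pvalues(
    counts,
    rho_obs: pd.DataFrame | np.ndarray | None = None,
    n_boot: int = 100,
    rng_seed: int = 0,
    n_exclusion_iter: int = 10,
    exclusion_threshold: float = 0.1,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Two-sided permutation pseudo p-values for SparCC correlations.

    Each bootstrap permutes every taxon's counts across samples
    independently (destroying correlation, preserving margins) and
    recomputes SparCC.  p_ij = (1 + #{|rho_boot| >= |rho_obs|}) / (n_boot
    + 1), so p is never exactly 0.
    """
    if n_boot < 20:
        raise BiocrustError("n_boot must be >= 20")
    mat, taxa = _as_matrix(counts)
    if rho_obs is None:
        rho_obs = sparcc_correlations(
            mat, n_exclusion_iter, exclusion_threshold, pseudocount
        ).rho.to_numpy()
    elif isinstance(rho_obs, pd.DataFrame):
        rho_obs = rho_obs.to_numpy()
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 91]))
    abs_obs = np.abs(rho_obs)
    exceed = np.zeros_like(abs_obs)
    for _ in range(n_boot):
        perm = np.vstack([rng.permutation(row) for row in mat])
        rho_b = sparcc_correlations(
            perm, n_exclusion_iter, exclusion_threshold, pseudocount
        ).rho.to_numpy()
        exceed += np.abs(rho_b) >= abs_obs
    pval = (1.0 + exceed) / (n_boot + 1.0)
    np.fill_diagonal(pval, np.minimum(1.0 / (n_boot + 1.0), 1.0))
    pval = np.minimum(pval, 1.0)
    return pd.DataFrame((pval + pval.T) / 2.0, index=taxa, columns=taxa)


def sparcc_with_pvalues(
    counts,
    n_boot: int = 100,
    rng_seed: int = 0,
    n_exclusion_iter: int = 10,
    exclusion_threshold: float = 0.1,
    pseudocount: float = 1.0,
) -> CorrelationResult:
    """Convenience wrapper: correlations plus bootstrap p-values."""
    res = sparcc_correlations(counts, n_exclusion_iter, exclusion_threshold, pseudocount)
    pval = bootstrap_pvalues(
        counts,
        res.rho,
        n_boot=n_boot,
        rng_seed=rng_seed,
        n_exclusion_iter=n_exclusion_iter,
        exclusion_threshold=exclusion_threshold,
        pseudocount=pseudocount,
    )
    return CorrelationResult(rho=res.rho, pval=pval, n_boot=n_boot, excluded_pairs=res.excluded_pairs)
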