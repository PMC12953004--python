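# Methods

This note documents the models, null models, estimators and numerical
choices implemented in `biocrustnet`, and what the synthetic-data
generators do and do not emulate.

## Phylogenetic null model (βMNTD / βNTI)

βMNTD is computed abundance-weighted: each taxon contributes the
distance to its phylogenetically nearest taxon in the paired community,
weighted by relative abundance, averaged over both directions.  Shared
taxa contribute zero in both the observed and null statistic.

The null randomises the assignment of taxa to tree tips across the full
taxon pool of the table the two samples come from, preserving each
community's richness and abundance vector while destroying phylogenetic
relationships.  βNTI is the z-score of the observed βMNTD against
`n_null` such draws (default 999; the Monte-Carlo standard error of the
null mean at 999 draws resolves the ±2 decision boundary comfortably).
Classification uses strict inequalities — βNTI < −2 homogeneous
selection, > +2 variable selection, otherwise stochastic — so values at
exactly ±2 are stochastic.  Degenerate cases are explicit: a
self-comparison (or any pair whose null has zero spread) returns NaN
with a warning and is labelled `unclassified` rather than silently
classified.  βNTI is invariant to uniform rescaling of branch lengths,
which the suite checks as a property.

For six or fewer taxa the null can be enumerated exhaustively (all
tip-label permutations); the test suite uses this as the oracle for the
Monte-Carlo implementation.

Per-stage process fractions are computed over within-stage sample pairs
by default (C(9,2) = 36 pairs per stage in the standard design); an
`within_stage=False` mode evaluates all pairs, which is where
variable selection between stages becomes visible.  Cyanobacteria can
be excluded from the analysis by flag, since diversity analyses of the
non-cyanobacterial bacterial fraction are common in this field.

## Synthetic communities and the selection regimes

The phylogeny is simulated under a pure-birth (Yule) process at unit
rate: waiting times are exponential in the number of extant lineages
and a final waiting time is appended so every branch length is strictly
positive.

Communities are drawn per sample as a fixed-richness subset
(`richness_fraction`, default 0.25 of the taxon pool) of a stage-level
taxon pool, with per-sample log-normal noise on inclusion weights so
replicates contain different but equally structured subsets.  Under
selection regimes the stage pool is a contiguous window of the tree's
tip order centred on an anchor tip.  Tip-order neighbours share recent
ancestry, so the window is a phylogenetically coherent neighbourhood;
its width shrinks exponentially with `selection_strength` from the
whole tree (strength 0) towards 1.4× the per-sample richness.  The
floor of 1.4× is deliberate: narrower pools make replicates share
almost all taxa, and shared taxa carry no signal in the null (their
nearest-taxon distance is zero on both sides), so the βNTI contrast is
strongest when replicates overlap partially, not fully.  On a raw
pure-birth tree most tips are nearly equidistant from any anchor —
distances concentrate near twice the tree height — which is why the
pool is defined through tip-order adjacency rather than a smooth decay
of raw cophenetic distance.

`homogeneous` uses one anchor for all stages; `variable` spaces anchors
evenly around the tip order so stage pools barely overlap; `neutral`
samples uniformly.  The regime scale is artifact-defined; at the
documented default (`selection_strength = 8`, 200 taxa, depth 10⁴)
homogeneous selection is the modal within-stage class and neutral data
are > 80 % stochastic, while the variable regime shows βNTI ≫ +2 on
across-stage pairs.  Mean within-stage βNTI under the homogeneous
regime typically falls between −1 and −2.5 across tree/seed
realisations; the regime *ranking* is stable even when the modal-class
margin is not.

Abundances are log-normal (mean-log uniform in [log 10, log 1000],
sd-log 1) with a per-stage effect (sd 0.5) and per-sample noise
(sd 0.5); each sample is a multinomial draw of `seq_depth` reads, so
column sums equal the configured depth exactly.  Taxonomy is synthetic:
fungi are one clade (~25 % of tips), cyanobacteria one clade inside the
bacteria (~`cyano_fraction` of tips, default 20 %, phylum
`Cyanobacteria`), families contiguous blocks of tips.

What the generator does **not** emulate: sequence errors and chimeras,
taxon-specific amplification bias, overdispersion beyond multinomial
sampling, mixed 16S/ITS library designs, or real lineage names.
Passing recovery tests therefore demonstrates correctness of the
estimators under idealised compositional sampling, not performance on
raw amplicon data.

## Planted-correlation counts

Correlated basis abundances come from a Gaussian copula on the log
scale: the planted pair list is embedded in a correlation matrix,
projected to the nearest positive semi-definite correlation matrix
(eigenvalue clipping at 1e-10, rescaled to unit diagonal) so arbitrary
pair lists are usable, then Cholesky-factored.  The ground truth
returned to callers is the *repaired* matrix, which is what recovery
should be measured against.  log x = μ + Lz gives exactly the planted
correlations on the log scale — the scale on which SparCC's basis
correlations are defined.

## SparCC

The estimator follows the classical log-ratio-variance construction.
Zeros are handled by one deterministic transform: each sample is
rescaled to a common pseudo-depth (default 10⁴), offset by a +1
pseudocount, and renormalised.  Because rescaling precedes the
pseudocount, the estimate is *exactly* invariant to per-sample
multiplicative factors (library-size differences); the suite asserts
invariance to 1e-9.  The pseudo-depth bounds the information retained
per sample — zeros behave like counts at depth 10⁴ regardless of the
true library size — which is an acceptable trade for exact
compositional invariance at the depths this pipeline targets.

The basis-variance system is solved from the row sums of t under the
sparsity assumption; exclusion iterations remove the single
strongest-|ρ| pair above 0.1 (up to 10 rounds) and re-solve, the
original SparCC heuristic.  Pairs are only excluded while both taxa
keep at least two included partners, which keeps the linear system
non-singular; if it degenerates anyway the solve falls back to least
squares with a warning.  Negative basis variances are floored at 1e-10
with a warning; ρ is clipped to [−1, 1].

Pseudo p-values permute every taxon's counts across samples
independently (margins preserved, all correlation destroyed) and use
the add-one estimator p = (1 + #{|ρ_boot| ≥ |ρ_obs|})/(n_boot + 1), so
p is never 0 and its minimum is 1/(n_boot+1).  No multiple-testing
correction is applied by default because the network edge filter uses
raw p ≤ 0.05; a Benjamini-Hochberg step can be applied downstream by
the caller if desired.

At the reference setting (50 taxa, 100 samples, depth 5·10⁴) planted
correlations of |ρ| ∈ {0.6, 0.8, 0.9} are recovered with maximum
absolute error well under 0.15 and independent pairs average |ρ̂| < 0.1
(see `scripts/acceptance.py`).

## Networks, roles, stability

Edges require |ρ| ≥ 0.65 and p ≤ 0.05, both inclusive as printed
conventionally; the magnitude is used so that negative co-occurrences
pass the filter, with the sign retained as an edge attribute.  The
abundance filter keeps taxa with overall relative abundance strictly
above 0.1 % and non-zero counts in at least 7 replicates of the focal
stage; networks are built per successional stage.

Module detection is greedy (Clauset–Newman–Moore) modularity
maximisation.  To make partitions reproducible across processes the
graph is relabelled to integers in sorted-node order first (string hash
randomisation otherwise perturbs tie-breaking), and module ids are
assigned by each module's smallest member.

Zi uses the mean/sd of within-module degree over the node's own module
(Zi = 0 when the sd is 0); Pi = 1 − Σ_s (k_is/k_i)², zero for isolated
nodes.  Role thresholds are Zi = 2.5 and Pi = 0.62, with boundary
values peripheral (strict inequalities on the keystone side).

Robustness removes nodes (random subsets of a given fraction, a
restricted pool such as the cyanobacterial nodes, or a targeted ordered
list) and then iteratively deletes nodes whose degree has dropped to
zero — an unweighted secondary-extinction cascade; the statistic is the
proportion of original nodes remaining.  The cascade is idempotent and
targeted curves are non-increasing, both asserted as properties.  An
abundance-weighted cascade variant is deliberately not implemented; the
unweighted isolation rule is the default reading of the species-loss
framework this follows.

Vulnerability is max_i (E − E_{−i})/E with E the global efficiency
(mean inverse shortest-path length over unordered pairs, 0 for
disconnected pairs).  Closed forms: a 3-path has vulnerability 1
(removing the middle vertex disconnects the rest), complete graphs 0.

The Ctr/Cyr contrast builds the 'without' network by deleting the
focal group's nodes and incident edges from the same constructed
network, runs 100 random-removal permutations on each, and compares the
replicate robustness values with a two-sided Welch t-test
(Mann-Whitney by flag).  If the group has no presence in the network
the two networks coincide and the same removal seed is reused, so the
contrast is exactly null (p = 1).

The planted-keystone generator wires near-equal Erdős–Rényi modules
(p_within inside, p_between across), designates one hub per module
(wired to every module member) and a configurable number of connectors
(each wired to 25 % of every module).  Dense settings
(p_within = 0.6) are used for Zi-Pi recovery; sparse settings
(p_within = 0.05, no between-module noise) produce fragile networks in
which the connectors carry the inter-module redundancy, the
configuration used for the group-removal contrast.

## Pipeline and determinism

All randomness flows from one integer seed through
`numpy.random.SeedSequence` with fixed per-component salts, so every
stage (tree, communities, rarefaction draws, null permutations,
bootstraps, removal permutations) has an independent but reproducible
stream.  Rarefaction uses multivariate-hypergeometric draws (without
replacement); samples below the target depth (default 1648 reads) are
dropped with a warning.  The full pipeline writes plain TSV, GraphML
and Gephi CSVs with a fixed float format, plus a JSON manifest of
configuration, seed, library versions and input checksums; two runs
with the same configuration are byte-identical, which both the suite
and the acceptance script verify.

Default problem sizes (200 taxa / 36 samples for assembly runs, 50
taxa / 100 samples for correlation recovery, 80–100-node networks, 999
null draws, 100 bootstrap and removal permutations) were chosen so the
whole chain, including the exhaustive-enumeration oracles, runs
comfortably on a single CPU while keeping the Monte-Carlo error of
every statistic small relative to its decision thresholds.

## Known limitations

- The βNTI magnitudes attainable on pure-birth trees at these richness
  scales are modest (|βNTI| of 2–4); real amplicon phylogenies with
  thousands of tips and strong rate heterogeneity yield larger
  magnitudes.  Threshold-based conclusions transfer; effect sizes do
  not.
- The stochastic class is not further partitioned (no RCbray step into
  dispersal limitation vs drift).
- SparCC's Dirichlet-resampling variant of zero handling is not
  implemented; the deterministic pseudocount path is the only one.
- Tree inference, ordination, PERMANOVA-style testing and plotting are
  out of scope; trees and stage labels are inputs.
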