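# Methods

## Model and objective

A cell's measured UMI counts are taken to be a multinomial sample, of size
equal to the cell's total count `N_c`, of its gene expression state (GES) —
the vector of transcription quotients `α⃗` on the gene simplex. This follows
from Poisson-distributed mRNA counts and per-transcript capture with an
unknown per-cell rate, once the capture rate is marginalised out and the
total is conditioned on. The hypothesis space is the set of partitions of
the cells into non-empty clusters, each cluster sharing one GES.

Within a cluster `s`, the product of the member cells' multinomials depends
on the data only through the aggregated counts `n_gs` and total `N_s`.
Marginalising the shared `α⃗_s` against a Dirichlet prior with
concentrations `θ_g` (the unique prior family invariant under rescaling of
the unobservable absolute transcription activities) gives the
Dirichlet-multinomial marginal — a ratio of products of Gamma functions:

    log P(n⃗_s) = lnΓ(θ) − lnΓ(θ + N_s) + Σ_g [lnΓ(θ_g + n_gs) − lnΓ(θ_g)],
    θ = Σ_g θ_g.

Per-cell multinomial coefficients `N_c!/Π_g n_gc!` are identical for every
partition and are dropped everywhere; all reported log-likelihoods are
therefore defined up to one data constant (stated in output manifests), and
all likelihood *ratios* between partitions are exact. With flat priors over
partitions and over the prior parameters, the posterior is proportional to
the product of cluster marginals; the program jointly maximises it over the
partition and the prior.

### Prior parametrisation

The concentrations are parametrised as a scalar strength times a base
measure, `θ_g = θ·π_g`, with two base measures available: *empirical*
(`π_g ∝` dataset-wide gene totals + 1 pseudocount; default) and *uniform*.
Only the scalar `θ` is optimised — a one-dimensional bounded Brent search on
`log θ` (relative tolerance 1e-4, default bracket `[1e-2, 1e7]`). This keeps
the joint optimisation tractable while respecting the rescaling invariance;
a fully per-gene free prior would add thousands of coupled parameters to
what is already a combinatorial search. The schedule: `θ` is fitted once on
the all-singletons partition, then re-fitted after each MCMC + refinement
round, iterating to joint convergence (at most 5 outer rounds or a
log-likelihood gain below 1e-3).

## Search

Starting from all singletons, each MCMC proposal moves a uniformly chosen
cell to a uniformly chosen target among the other clusters plus a NEW
cluster (splits must stay reachable after merges, otherwise the chain is not
irreducible from coarse states; NEW is excluded for cells that are already
singlets). Improving moves are always accepted; a non-improving move with
log-likelihood change `d ≤ 0` is accepted with probability
`exp(d) · (targets before)/(targets after)` — the standard
Metropolis–Hastings correction for the changing size of the uniform proposal
set. In practice `|d|` is large for almost all proposals (totals per cell
are in the thousands), so the sampler behaves as a random uphill walk; a
pure uphill mode (`uphill_only`) is available and is used by monotonicity
tests.

Convergence is declared after `20·n_cells` consecutive proposals without an
accepted improving move, with a hard cap of 1000 sweeps (one sweep =
`n_cells` proposals). Afterwards deterministic refinement repeats to a
fixpoint: (a) per cell in index order, apply the best strictly-improving
move over all clusters and NEW (ties to the lowest cluster index); (b) per
cluster pair in ascending index order, merge when the pair's merge log-ratio
is positive. The final state is a local optimum under single moves and pair
merges. Multiple restarts run on consecutive seeds (`seed + r`) and the best
final likelihood wins.

Numerics: the inner loops run as compiled kernels; `lnΓ(θ_g + k)` values for
integer `k` are served from a per-gene lookup table (capped at k < 4096 by
default, with direct evaluation beyond — cluster gene counts are bounded by
gene totals, so the cap only matters for the most abundant genes). The
running total log-likelihood is accumulated from move deltas and re-derived
from scratch at phase boundaries to eliminate float drift. Strict
improvement uses a 1e-10 threshold so float noise cannot produce cycling.

Breakpoints store the exact search state — slot-level assignment, active and
free cluster lists, prior, RNG state, trace, and a checksum of the matrix —
so a resumed run is bit-identical to an uninterrupted one on the same seed
stream. Incremental partitioning appends new cells as singletons to an
existing partition (gene universes reconciled by intersection) and
re-optimises jointly; the result is guarded to never fall below the naive
union's likelihood.

## Hierarchy

Pairwise cluster similarity is the likelihood ratio merged/separate;
distance is its negative logarithm. The maximal-ratio pair is merged
iteratively (ties to the lexicographically smallest pair); only pairs
involving the new cluster are recomputed, which is exact because a pair's
ratio depends only on the two clusters' own counts. At the search's output
every ratio is negative (otherwise refinement would have merged the pair),
but ratios can turn positive after a few merges; raw heights (cumulative
summed distances, equal to the relative negative log-likelihood of each
intermediate partition) are preserved in the merge table, and Newick export
monotonicises them by cumulative maximum for display. `θ` is held fixed at
the fitted value during tree building; re-fitting it per merge would change
the objective mid-hierarchy and the likelihood ratios would no longer be
comparable across levels.

## Gene scores

*Differential expression across a branch.* Collapsing the
Dirichlet-multinomial to two categories (gene `g` vs. the rest) yields a
Beta-binomial analogue of the pair merge ratio per gene; this is the unique
two-category reduction consistent with the aggregation property of the
Dirichlet-multinomial. Most-negative scores oppose merging most strongly —
they are the most significantly differentially *averaged* genes. The gene
sum only approximates the exact pair ratio (genes are not independent under
the multinomial constraint); on random well-separated fixtures the observed
relative deviation is roughly 2–26%, which the test suite logs and bounds
rather than asserting exactness. Genes with zero counts on both sides score
exactly 0 by convention.

*Markers.* For each gene the per-cellstate posterior-mean quotients are
compared between the two sides as distributions, each cellstate counting
once regardless of size. The score is the maximal gap between the two
empirical CDFs (a Kolmogorov–Smirnov statistic): 1 for a perfectly
separating gene, 0 for identical distributions. An equivalent reading:
`1 − 2·overlap`, where overlap is the best achievable equal-weighted
threshold classification error. A threshold rule on a single gene is what a
bench scientist can act on, which is why marker scoring deliberately differs
from DE scoring.

## Simulator

`sample_ground_truth` draws: a shared heavy-tailed gene base measure
(symmetric Dirichlet, 0.5 per gene — expression spanning orders of
magnitude); state quotients around it (Dirichlet with total concentration
1000 by default, giving order-100% per-gene variation between states —
clearly distinct states that still share global structure); state abundances
from a power law (exponent 1.5), so realised cluster sizes span orders of
magnitude and the tail yields singlets; and log-normal cell totals (median
2000, σ = 0.6 in log-space, emulating library-size spread). Unrealised tail
states are dropped, so every state in the returned truth has at least one
cell. `sample_counts` then draws each cell multinomially from its state —
exactly the noise model the likelihood assumes.

What the simulator does *not* emulate: batch effects, doublets,
gene-specific capture bias, ambient RNA, or continuous trajectories between
states. Passing the recovery benchmark therefore shows that the search finds
the optimum of its own objective on data obeying the model, not that real
tissues consist of discrete states.

The desk-scale benchmark — 20 datasets × (800 cells, 1000 genes, 30 states,
median total 2000), 3 optimizer runs each — was sized to exercise realistic
per-dataset structure (including singlet states) while the full experiment
completes in minutes on one CPU. At these settings pairwise generating-state
merge log-ratios are in the thousands of nats, so near-exact recovery is the
expected outcome; recovery degrades on shallower or less concentrated draws
(see `downsample` for controlled degradation).

## Evaluation

Homogeneity and completeness are the entropy-based V-measure components,
computed in nats from the joint contingency table (the base cancels in the
ratios). Degenerate conventions: `H(C)=0 ⇒ homogeneity=1`,
`H(K)=0 ⇒ completeness=1`. The exact symmetry
`homogeneity(ρ, ρ_f) = completeness(ρ_f, ρ)` is tested, and the
implementation is cross-checked against scikit-learn's independent one in
the test suite only (it is not a runtime dependency of the package).

## Known limitations

- The search is a stochastic local optimiser; no run guarantees the global
  optimum. Restarts and the exhaustive-enumeration test on tiny problems
  bound the practical risk.
- Runtime grows with cells × per-cell nonzeros; datasets beyond ~10^5 cells
  call for the incremental mode.
- The Beta-binomial DE score is an approximation to the exact per-branch
  likelihood ratio (see above).
- A scalar-strength Dirichlet prior cannot express gene-specific prior
  dispersion; the base measure absorbs mean abundance only.
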