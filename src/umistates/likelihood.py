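"""Exact marginal log-likelihood of a partition under the Dirichlet-multinomial model.

For a cluster ``s`` with aggregated counts ``n_gs`` (total ``N_s``) and a
Dirichlet prior with concentrations ``theta_g`` (sum ``theta``), integrating
the shared multinomial parameter out analytically gives the multivariate-Beta
ratio

    log P(n_s | theta) = lnG(theta) - lnG(theta + N_s)
                         + sum_g [lnG(theta_g + n_gs) - lnG(theta_g)]

up to the per-cell multinomial coefficients ``N_c! / prod_g n_gc!``.  Those
coefficients are identical for every partition of the same data, so they are
dropped throughout; all log-likelihoods reported by this package are therefore
"up to a data constant", and all likelihood *ratios* between partitions are
exact.  The sum may be restricted to genes with ``n_gs > 0``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln
from scipy.optimize import minimize_scalar

from .data import CountMatrix, DirichletPrior, Partition, DataError, NEW, move_cell

__all__ = [
    "cluster_log_marginal",
    "partition_log_likelihood",
    "LogLikelihoodLedger",
    "delta_move",
    "pair_merge_log_ratio",
    "optimize_prior_strength",
]


def cluster_log_marginal(counts, total=None, prior: DirichletPrior = None) -> float:
    """Log Dirichlet-multinomial marginal of one cluster (up to data constant).

    Parameters
    ----------
    counts : integer array, shape (n_genes,)
        Aggregated cluster counts ``n_gs``.
    total : int, optional
        ``N_s = sum_g n_gs``; recomputed (and checked) if given.
    prior : DirichletPrior

    Returns
    -------
    float
        ``log[ B(theta_vec + n_s) / B(theta_vec) ]``; 0 for an all-zero
        cluster (an empty cluster contributes nothing).
    """
    counts = np.asarray(counts)
    if counts.dtype.kind == "f":
        if not np.all(counts == np.floor(counts)):
            raise DataError("cluster counts must be integers")
        counts = counts.astype(np.int64)
    if np.any(counts < 0):
        raise DataError("cluster counts must be non-negative")
    n_total = int(counts.sum())
    if total is not None and int(total) != n_total:
        raise DataError(f"total {total} != sum of counts {n_total}")
    if prior is None:
        raise DataError("a DirichletPrior is required")
    if prior.n_genes != counts.size:
        raise DataError("prior dimension does not match counts")
    if n_total == 0:
        return 0.0
    nz = np.flatnonzero(counts)
    th = prior.concentrations[nz]
    out = gammaln(prior.concentration_sum) - gammaln(prior.concentration_sum + n_total)
    out += float(np.sum(gammaln(th + counts[nz]) - gammaln(th)))
    return float(out)


class LogLikelihoodLedger:
    """Per-cluster log-marginal terms of a partition, with their total.

    ``total_loglik`` is the sum of ``per_cluster_loglik`` (cluster index ->
    term); the ledger caches the prior it was computed under.
    """

    def __init__(self, per_cluster_loglik: dict, prior: DirichletPrior):
        self.per_cluster_loglik = dict(per_cluster_loglik)
        self.prior_ref = prior

    @property
    def total_loglik(self) -> float:
        return float(sum(self.per_cluster_loglik.values()))

    def check(self, partition: Partition, rtol: float = 1e-9) -> None:
        for k, v in self.per_cluster_loglik.items():
            ref = cluster_log_marginal(
                partition.cluster_counts[k], partition.cluster_totals[k], self.prior_ref
            )
            if abs(ref - v) > rtol * max(1.0, abs(ref)):
                raise AssertionError(f"ledger term for cluster {k} is stale")


def partition_log_likelihood(
    partition: Partition, prior: DirichletPrior
) -> LogLikelihoodLedger:
    """Ledger of per-cluster marginals; the partition's total log-likelihood
    is the sum over clusters (the product of per-cluster likelihoods)."""
    terms = {}
    for k in range(partition.n_clusters):
        terms[k] = cluster_log_marginal(
            partition.cluster_counts[k], partition.cluster_totals[k], prior
        )
    return LogLikelihoodLedger(terms, prior)


def _delta_leave(partition: Partition, prior: DirichletPrior, cell: int, src: int) -> float:
    """Change in the source cluster's term when `cell` leaves cluster `src`."""
    genes, cnts = partition.matrix.cell_counts(cell)
    nc = int(partition.matrix.cell_totals[cell])
    th = prior.concentrations[genes]
    ns = partition.cluster_counts[src, genes]
    d = gammaln(prior.concentration_sum + partition.cluster_totals[src])
    d -= gammaln(prior.concentration_sum + partition.cluster_totals[src] - nc)
    d += float(np.sum(gammaln(th + ns - cnts) - gammaln(th + ns)))
    # when the cluster empties, lnG(theta + 0) = lnG(theta) makes this -L(src)
    return float(d)


def _delta_join(partition: Partition, prior: DirichletPrior, cell: int, tgt) -> float:
    """Change in the target cluster's term when `cell` joins (`tgt` may be NEW)."""
    genes, cnts = partition.matrix.cell_counts(cell)
    nc = int(partition.matrix.cell_totals[cell])
    th = prior.concentrations[genes]
    if tgt is NEW:
        nt, tot = np.zeros_like(cnts), 0
    else:
        nt = partition.cluster_counts[int(tgt), genes]
        tot = int(partition.cluster_totals[int(tgt)])
    d = gammaln(prior.concentration_sum + tot) - gammaln(
        prior.concentration_sum + tot + nc
    )
    d += float(np.sum(gammaln(th + nt + cnts) - gammaln(th + nt)))
    # for tgt=NEW, lnG(theta + 0) = lnG(theta) makes this L(singleton cell)
    return float(d)


def delta_move(
    ledger: LogLikelihoodLedger,
    partition: Partition,
    prior: DirichletPrior,
    cell: int,
    target,
) -> float:
    """Log-likelihood change of moving ``cell`` to ``target`` (or ``NEW``).

    Touches only the source cluster, the target cluster, and the moved cell's
    nonzero genes; equals the difference of full recomputations to ~1e-8.
    """
    src = int(partition.assignment[cell])
    if target is not NEW:
        tgt = int(target)
        if not (0 <= tgt < partition.n_clusters):
            raise DataError(f"unknown cluster {target}")
        if tgt == src:
            raise DataError("cannot move a cell to its own cluster")
    return _delta_leave(partition, prior, cell, src) + _delta_join(
        partition, prior, cell, target if target is NEW else int(target)
    )


def pair_merge_log_ratio(
    partition: Partition, prior: DirichletPrior, cluster_a: int, cluster_b: int
) -> float:
    """Log likelihood-ratio of merging two clusters versus keeping them apart.

    ``log P(merged) - log P(a) - log P(b)``; symmetric in its arguments.  At
    the optimal partition this is negative for every pair (otherwise merging
    would improve the partition).  Its negation is the hierarchy's distance.
    """
    a, b = int(cluster_a), int(cluster_b)
    if a == b:
        raise DataError("pair_merge_log_ratio requires two distinct clusters")
    ca, cb = partition.cluster_counts[a], partition.cluster_counts[b]
    ta, tb = int(partition.cluster_totals[a]), int(partition.cluster_totals[b])
    return (
        cluster_log_marginal(ca + cb, ta + tb, prior)
        - cluster_log_marginal(ca, ta, prior)
        - cluster_log_marginal(cb, tb, prior)
    )


def _pack_nonzeros(partition: Partition):
    """Flatten (cluster, gene, count) triplets of all nonzero cluster counts."""
    kk, gg = np.nonzero(partition.cluster_counts)
    return gg, partition.cluster_counts[kk, gg], partition.cluster_totals


def optimize_prior_strength(
    partition: Partition,
    base_measure,
    bracket=(1e-2, 1e7),
    rtol: float = 1e-4,
):
    """Maximise the partition log-likelihood over the prior strength theta.

    One-dimensional deterministic (bounded Brent) search on log(theta) within
    ``bracket``; the base measure is held fixed.  Returns ``(theta_star,
    loglik_star)`` with ``loglik_star`` the log-likelihood at the optimum.
    """
    base_measure = np.asarray(base_measure, dtype=np.float64)
    gg, cnt, totals = _pack_nonzeros(partition)
    pig = base_measure[gg]
    k = partition.n_clusters
    lo, hi = bracket
    if not (0 < lo < hi):
        raise DataError("bracket endpoints must be positive and increasing")

    def negloglik_of_log(x):
        th = np.exp(x)
        val = k * gammaln(th) - float(np.sum(gammaln(th + totals)))
        val += float(np.sum(gammaln(th * pig + cnt) - gammaln(th * pig)))
        if not np.isfinite(val):
            raise DataError(f"non-finite likelihood at theta={th}")
        return -val

    res = minimize_scalar(
        negloglik_of_log,
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": rtol / 2},
    )
    theta_star = float(np.exp(res.x))
    loglik = -negloglik_of_log(res.x)
    # guard against a bracket-edge maximum the bounded search missed
    for edge in (np.log(lo), np.log(hi)):
        v = -negloglik_of_log(edge)
        if v > loglik:
            theta_star, loglik = float(np.exp(edge)), v
    return theta_star, float(loglik)
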