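"""Per-gene differential-expression and marker scores between two sets of cellstates.

Two complementary rankings:

* :func:`de_scores` measures how much each gene opposes merging the two
  sides.  Collapsing the Dirichlet-multinomial to two categories (gene g
  versus the rest) gives a Beta-binomial merge log-ratio per gene; the most
  negative scores are the most significantly differentially expressed in
  *average* expression, and their sum approximates the full pairwise merge
  log-ratio of the aggregated sides.

* :func:`marker_scores` measures how well a single gene separates the two
  sets of cellstates, as the maximal gap between the cumulative
  distributions of per-cellstate posterior-mean quotients on either side
  (a Kolmogorov-Smirnov-style statistic in [0, 1]; 1 = perfectly separating,
  0 = identical distributions).  Each cellstate counts once regardless of
  its size, so one giant cellstate cannot dominate the ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .data import DataError, DirichletPrior, Partition

__all__ = ["GeneScoreTable", "de_scores", "marker_scores"]


@dataclass
class GeneScoreTable:
    """Per-gene score table; ``frame`` carries one row per gene.

    Common columns: gene, counts_a, counts_b, mean_a, mean_b (posterior-mean
    quotients of the aggregated sides), higher_side.  ``de_log_score`` is
    present after :func:`de_scores` (sorted ascending: most differentially
    expressed first); ``marker_score`` after :func:`marker_scores` (sorted
    descending: best markers first).
    """

    frame: pd.DataFrame

    def top(self, n: int = 20) -> pd.DataFrame:
        return self.frame.head(n)

    def sorted_by(self, column: str, ascending: bool = True) -> pd.DataFrame:
        return self.frame.sort_values(
            column, ascending=ascending, kind="mergesort"
        )

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def _check_sides(side_a, side_b, partition):
    a = sorted(int(s) for s in side_a)
    b = sorted(int(s) for s in side_b)
    if not a or not b:
        raise DataError("both sides must contain at least one cellstate")
    if set(a) & set(b):
        raise DataError(f"sides overlap: {sorted(set(a) & set(b))}")
    for s in a + b:
        if not (0 <= s < partition.n_clusters):
            raise DataError(f"unknown cellstate {s}")
    return a, b


def _aggregate(partition, side):
    counts = partition.cluster_counts[side].sum(axis=0)
    total = int(partition.cluster_totals[side].sum())
    return counts, total


def de_scores(side_a, side_b, partition: Partition, prior: DirichletPrior
              ) -> GeneScoreTable:
    """Beta-binomial per-gene merge log-ratio between two sides.

    For gene ``g`` with side counts ``x_A, x_B`` out of totals ``N_A, N_B``
    and prior ``(theta_g, theta - theta_g)``:

        score_g = logBB(x_A + x_B, N_A + N_B) - logBB(x_A, N_A)
                  - logBB(x_B, N_B)

    with ``logBB(x, N) = lnB(theta_g + x, theta - theta_g + N - x)
    - lnB(theta_g, theta - theta_g)``.  Genes absent from both sides score
    exactly 0.  Symmetric under swapping the sides; the table is sorted
    ascending (most negative = most significant).
    """
    a, b = _check_sides(side_a, side_b, partition)
    ca, na = _aggregate(partition, a)
    cb, nb = _aggregate(partition, b)
    th = prior.concentrations
    ts = prior.concentration_sum

    def log_bb(x, n):
        # lnB(theta_g + x, theta - theta_g + n - x) - lnB(theta_g, theta - theta_g)
        return (
            gammaln(th + x)
            + gammaln(ts - th + n - x)
            - gammaln(ts + n)
            - (gammaln(th) + gammaln(ts - th) - gammaln(ts))
        )

    score = log_bb(ca + cb, na + nb) - log_bb(ca, na) - log_bb(cb, nb)
    score[(ca + cb) == 0] = 0.0

    mean_a = (ca + th) / (na + ts)
    mean_b = (cb + th) / (nb + ts)
    frame = pd.DataFrame(
        {
            "gene": partition.matrix.gene_ids,
            "de_log_score": score,
            "higher_side": np.where(mean_a >= mean_b, "a", "b"),
            "counts_a": ca,
            "counts_b": cb,
            "mean_a": mean_a,
            "mean_b": mean_b,
        }
    ).sort_values("de_log_score", kind="mergesort", ignore_index=True)
    return GeneScoreTable(frame)


def _ks_distance(va: np.ndarray, vb: np.ndarray) -> float:
    """max_t |F_a(t) - F_b(t)| over the pooled sample points."""
    pool = np.concatenate([va, vb])
    pool.sort()
    fa = np.searchsorted(np.sort(va), pool, side="right") / va.size
    fb = np.searchsorted(np.sort(vb), pool, side="right") / vb.size
    return float(np.max(np.abs(fa - fb)))


def marker_scores(side_a, side_b, partition: Partition, prior: DirichletPrior
                  ) -> GeneScoreTable:
    """Distribution-overlap marker score per gene.

    For each gene the per-cellstate posterior-mean quotients are computed on
    both sides (each cellstate weighted equally); the marker score is the
    maximal difference between the two empirical CDFs.  A gene distinctly
    expressed in every side-a cellstate and at baseline in every side-b
    cellstate scores 1; identical distributions score 0.  Invariant under
    relabeling cellstates within a side.  Sorted descending.
    """
    a, b = _check_sides(side_a, side_b, partition)
    th = prior.concentrations
    ts = prior.concentration_sum
    qa = (partition.cluster_counts[a] + th) / (
        partition.cluster_totals[a][:, None] + ts
    )
    qb = (partition.cluster_counts[b] + th) / (
        partition.cluster_totals[b][:, None] + ts
    )
    G = partition.matrix.n_genes
    score = np.empty(G)
    for g in range(G):
        score[g] = _ks_distance(qa[:, g], qb[:, g])

    ca, na = _aggregate(partition, a)
    cb, nb = _aggregate(partition, b)
    mean_a = (ca + th) / (na + ts)
    mean_b = (cb + th) / (nb + ts)
    frame = pd.DataFrame(
        {
            "gene": partition.matrix.gene_ids,
            "marker_score": score,
            "higher_side": np.where(qa.mean(axis=0) >= qb.mean(axis=0), "a", "b"),
            "counts_a": ca,
            "counts_b": cb,
            "mean_a": mean_a,
            "mean_b": mean_b,
        }
    ).sort_values("marker_score", kind="mergesort", ascending=False,
                  ignore_index=True)
    return GeneScoreTable(frame)
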