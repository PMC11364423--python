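"""Model/Results interface to the partition search.

:class:`PartitionModel` holds the data (a count matrix) and the prior
configuration; :meth:`PartitionModel.fit` runs the likelihood maximisation
and returns a :class:`PartitionResults` carrying the inferred partition, the
fitted prior strength, diagnostics, and convenience methods for the
downstream toolbox (hierarchy, gene scores, diversity, evaluation,
parametric resimulation).

Example
-------
>>> from umistates import PartitionModel, simulate
>>> truth = simulate.sample_ground_truth(n_states=5, n_genes=50, n_cells=60,
...                                      rng=0)
>>> counts, generating = simulate.sample_counts(truth, rng=1)
>>> res = PartitionModel(counts).fit(seed=0, n_runs=2)
>>> res.n_cellstates  # doctest: +SKIP
5
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import CountMatrix, DataError, DirichletPrior, Partition
from .evaluation import AgreementReport, DiversityReport, diversity, \
    homogeneity_completeness
from .gene_scores import GeneScoreTable, de_scores, marker_scores
from .hierarchy import MergeTree, build_merge_tree, cut_tree
from .likelihood import partition_log_likelihood
from .optimize import OptimizerConfig, RunResult, run, run_incremental

__all__ = ["PartitionModel", "PartitionResults"]


class PartitionModel:
    """Dirichlet-multinomial partition model of a UMI count matrix.

    Parameters
    ----------
    counts : CountMatrix, array-like, or scipy sparse (genes x cells)
        Raw UMI counts; anything array-like is wrapped in a
        :class:`CountMatrix` (zero-total genes dropped, zero-total cells
        rejected).
    theta_base : {"empirical", "uniform"}
        Base measure of the Dirichlet prior: proportional to dataset-wide
        gene totals (plus pseudocount), or flat over genes.
    prior : DirichletPrior, optional
        Fully specified prior; combined with ``optimize_theta=False`` it is
        held fixed during fitting.
    """

    def __init__(self, counts, gene_ids=None, cell_ids=None, *,
                 theta_base: str = "empirical",
                 prior: DirichletPrior | None = None,
                 optimize_theta: bool = True):
        if isinstance(counts, CountMatrix):
            self.data = counts
        else:
            self.data = CountMatrix(counts, gene_ids=gene_ids, cell_ids=cell_ids)
        if theta_base not in ("empirical", "uniform"):
            raise DataError("theta_base must be 'empirical' or 'uniform'")
        self.theta_base = theta_base
        self.prior = prior
        self.optimize_theta = optimize_theta

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame,
                       orientation: str = "genes-by-cells", **kwargs
                       ) -> "PartitionModel":
        """Build from a DataFrame (index = gene ids, columns = cell ids)."""
        if orientation == "cells-by-genes":
            frame = frame.T
        elif orientation != "genes-by-cells":
            raise DataError(f"unknown orientation {orientation!r}")
        return cls(frame.to_numpy(), gene_ids=list(frame.index.astype(str)),
                   cell_ids=list(frame.columns.astype(str)), **kwargs)

    @classmethod
    def from_anndata(cls, adata, layer: str | None = None, **kwargs
                     ) -> "PartitionModel":
        """Build from an AnnData object (cells x genes; transposed here)."""
        X = adata.layers[layer] if layer else adata.X
        import scipy.sparse as sp

        mat = X.T if sp.issparse(X) else np.asarray(X).T
        return cls(mat, gene_ids=list(adata.var_names),
                   cell_ids=list(adata.obs_names), **kwargs)

    def fit(self, seed: int = 0, n_runs: int = 1,
            config: OptimizerConfig | None = None, **config_kwargs
            ) -> "PartitionResults":
        """Maximise the partition likelihood; best of ``n_runs`` restarts."""
        if config is None:
            config = OptimizerConfig(
                seed=seed, n_runs=n_runs, theta_base=self.theta_base,
                optimize_theta=self.optimize_theta, **config_kwargs,
            )
        result = run(self.data, config, prior=self.prior)
        return PartitionResults(self, result, config)

    def loglik(self, partition_or_assignment, prior: DirichletPrior) -> float:
        """Log-likelihood of an arbitrary partition of this model's cells."""
        if isinstance(partition_or_assignment, Partition):
            part = partition_or_assignment
        else:
            from .data import build_partition

            part = build_partition(self.data, partition_or_assignment)
        return partition_log_likelihood(part, prior).total_loglik


class PartitionResults:
    """Fitted partition with its prior, diagnostics and downstream toolbox."""

    def __init__(self, model: PartitionModel, result: RunResult,
                 config: OptimizerConfig):
        self.model = model
        self.result = result
        self.config = config
        self._tree: MergeTree | None = None

    # -- estimates ----------------------------------------------------------
    @property
    def partition(self) -> Partition:
        return self.result.partition

    @property
    def prior(self) -> DirichletPrior:
        return self.result.prior

    @property
    def theta(self) -> float:
        return self.result.prior.strength

    @property
    def log_likelihood(self) -> float:
        return self.result.log_likelihood

    @property
    def n_cellstates(self) -> int:
        return self.partition.n_clusters

    @property
    def converged(self) -> bool:
        return self.result.converged

    @property
    def trace(self) -> np.ndarray:
        return self.result.trace

    def assignment_series(self) -> pd.Series:
        part = self.partition
        return pd.Series(
            [part.labels[k] for k in part.assignment],
            index=pd.Index(part.matrix.cell_ids, name="cell_id"),
            name="cellstate_id",
        )

    def ges_matrix(self) -> pd.DataFrame:
        """Posterior-mean transcription quotients, cellstates x genes."""
        part = self.partition
        rows = [part.ges(k, self.prior).quotients for k in range(part.n_clusters)]
        return pd.DataFrame(np.vstack(rows), columns=part.matrix.gene_ids,
                            index=[str(l) for l in part.labels])

    # -- downstream toolbox -------------------------------------------------
    def merge_tree(self, refresh: bool = False) -> MergeTree:
        if self._tree is None or refresh:
            self._tree = build_merge_tree(self.partition, self.prior)
        return self._tree

    def cut(self, k: int) -> Partition:
        """Partition into ``k`` higher-order clusters from the merge tree."""
        return cut_tree(self.merge_tree(), k)

    def de_scores(self, side_a, side_b) -> GeneScoreTable:
        return de_scores(side_a, side_b, self.partition, self.prior)

    def marker_scores(self, side_a, side_b) -> GeneScoreTable:
        return marker_scores(side_a, side_b, self.partition, self.prior)

    def branch_de_scores(self, node: int) -> GeneScoreTable:
        """DE scores between the two sides of a merge-tree branch."""
        a, b = self.merge_tree().branch_sides(node)
        return self.de_scores(a, b)

    def branch_marker_scores(self, node: int) -> GeneScoreTable:
        a, b = self.merge_tree().branch_sides(node)
        return self.marker_scores(a, b)

    def diversity(self) -> DiversityReport:
        return diversity(self.partition)

    def compare(self, reference) -> AgreementReport:
        """Homogeneity/completeness of this partition against a reference."""
        return homogeneity_completeness(self.partition, reference)

    def simulate(self, rng=None):
        """Parametric replicate: resample counts from the fitted cellstates.

        Each cell keeps its total UMI count and draws new counts
        multinomially from its cellstate's posterior-mean GES -- the same
        protocol used to validate the optimizer on data with known truth.
        Returns ``(CountMatrix, generating Partition)``.
        """
        from .simulate import GroundTruth, sample_counts

        part = self.partition
        quotients = np.vstack(
            [part.ges(k, self.prior).quotients for k in range(part.n_clusters)]
        )
        truth = GroundTruth(
            state_quotients=quotients,
            state_frequencies=part.cluster_sizes / part.n_cells,
            cell_assignment=part.assignment,
            cell_totals=part.matrix.cell_totals,
        )
        return sample_counts(truth, rng)

    def extend(self, new_cells, config: OptimizerConfig | None = None
               ) -> "PartitionResults":
        """Add new cells as singletons and re-optimize jointly (incremental
        partitioning); the result is never worse than the naive union."""
        if not isinstance(new_cells, CountMatrix):
            new_cells = CountMatrix(new_cells)
        result = run_incremental(new_cells, self.result, config or self.config)
        model = PartitionModel(result.partition.matrix,
                               theta_base=self.model.theta_base)
        return PartitionResults(model, result, config or self.config)

    def save(self, outdir):
        from .io import write_results

        echo = {k: v for k, v in vars(self.config).items()
                if isinstance(v, (int, float, str, bool, type(None), tuple))}
        echo = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in echo.items()}
        return write_results(self.result, outdir, config_echo=echo)

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        part = self.partition
        div = self.diversity()
        lines = [
            "Partition of UMI counts into gene expression states",
            "=" * 55,
            f"cells                 {part.n_cells:>12d}",
            f"genes                 {part.matrix.n_genes:>12d}",
            f"total UMIs            {part.matrix.total_count:>12d}",
            f"cellstates            {part.n_clusters:>12d}",
            f"singlets              {div.n_singlets:>12d}",
            f"singlet fraction      {div.singlet_fraction:>12.4f}",
            f"abundance entropy     {div.entropy:>12.4f}",
            f"prior strength theta  {self.theta:>12.4g}",
            f"log-likelihood*       {self.log_likelihood:>12.3f}",
            f"converged             {str(self.converged):>12s}",
            f"seed                  {self.result.seed:>12d}",
            f"runs                  {len(self.result.run_logliks) or 1:>12d}",
            "-" * 55,
            "* up to a partition-independent data constant",
        ]
        return "\n".join(lines)

    def __repr__(self):  # pragma: no cover
        return (
            f"<PartitionResults: {self.n_cellstates} cellstates, "
            f"loglik={self.log_likelihood:.3f}, theta={self.theta:.4g}>"
        )
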