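"""Core domain types: UMI count matrices, partitions, and the Dirichlet prior.

The measurement model treats the UMI counts ``n_gc`` of cell ``c`` as a
multinomial sample of size ``N_c`` from the cell's gene expression state
(GES), a probability vector of transcription quotients over genes.  A
:class:`Partition` groups cells that are hypothesised to share one GES and
caches the per-cluster aggregated counts ``n_gs`` and totals ``N_s`` that the
marginal likelihood is a function of.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: Sentinel target for :func:`move_cell`: create a fresh singleton cluster.
NEW = "NEW"


class DataError(ValueError):
    """Raised when input data violate the model's preconditions."""


class NoOpMove(Exception):
    """Signals that a proposed cell move is a no-op (target == current)."""


def _as_int_array(x, name):
    arr = np.asarray(x)
    if arr.dtype.kind == "f":
        if not np.all(arr == np.floor(arr)):
            bad = np.argwhere(arr != np.floor(arr))[0]
            raise DataError(f"{name} contains non-integer entry at {tuple(bad)}")
        arr = arr.astype(np.int64)
    elif arr.dtype.kind not in "iu":
        raise DataError(f"{name} must be integer-valued, got dtype {arr.dtype}")
    return arr.astype(np.int64)


class CountMatrix:
    """Genes x cells matrix of raw UMI counts.

    Parameters
    ----------
    counts : array-like or scipy sparse, shape (n_genes, n_cells)
        Non-negative integer UMI counts ``n_gc``.
    gene_ids, cell_ids : sequences of str, optional
        Unique identifiers; autogenerated (``g0..``, ``c0..``) if omitted.
    drop_zero_genes : bool
        Drop genes with zero total count (they contribute a constant to every
        partition's likelihood).  A warning with the number dropped is logged.

    Raises
    ------
    DataError
        On negative or non-integer counts, duplicate identifiers, or cells
        with zero total count (the multinomial conditions on ``N_c >= 1``;
        such cells must be filtered explicitly by the user).
    """

    def __init__(self, counts, gene_ids=None, cell_ids=None, *, drop_zero_genes=True):
        if sp.issparse(counts):
            mat = sp.csc_matrix(counts)
            mat.data = _as_int_array(mat.data, "counts")
        else:
            mat = sp.csc_matrix(_as_int_array(counts, "counts"))
        mat.eliminate_zeros()
        if mat.nnz and mat.data.min() < 0:
            raise DataError("counts contain negative entries")

        n_genes, n_cells = mat.shape
        if gene_ids is None:
            gene_ids = [f"g{i}" for i in range(n_genes)]
        if cell_ids is None:
            cell_ids = [f"c{i}" for i in range(n_cells)]
        gene_ids = np.asarray(gene_ids, dtype=object)
        cell_ids = np.asarray(cell_ids, dtype=object)
        if len(gene_ids) != n_genes or len(cell_ids) != n_cells:
            raise DataError(
                f"identifier lengths ({len(gene_ids)}, {len(cell_ids)}) do not "
                f"match matrix shape {mat.shape}"
            )
        if len(set(gene_ids)) != n_genes:
            raise DataError("gene_ids contain duplicates")
        if len(set(cell_ids)) != n_cells:
            raise DataError("cell_ids contain duplicates")

        gene_totals = np.asarray(mat.sum(axis=1)).ravel().astype(np.int64)
        if drop_zero_genes and np.any(gene_totals == 0):
            keep = gene_totals > 0
            n_dropped = int((~keep).sum())
            logger.warning("dropping %d genes with zero total count", n_dropped)
            mat = sp.csc_matrix(mat[keep, :])
            gene_ids = gene_ids[keep]
            gene_totals = gene_totals[keep]
            n_genes = mat.shape[0]

        cell_totals = np.asarray(mat.sum(axis=0)).ravel().astype(np.int64)
        if np.any(cell_totals == 0):
            bad = [str(cell_ids[i]) for i in np.flatnonzero(cell_totals == 0)[:10]]
            raise DataError(
                f"cells with zero total count are not allowed (filter them "
                f"explicitly): {bad}"
            )

        mat.sort_indices()
        self.counts: sp.csc_matrix = mat
        self.gene_ids = gene_ids
        self.cell_ids = cell_ids
        self.cell_totals = cell_totals
        self.gene_totals = gene_totals

    # -- basic geometry -----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def total_count(self) -> int:
        return int(self.cell_totals.sum())

    def cell_counts(self, c: int):
        """Return ``(gene_indices, counts)`` of the nonzero entries of cell c."""
        lo, hi = self.counts.indptr[c], self.counts.indptr[c + 1]
        return self.counts.indices[lo:hi], self.counts.data[lo:hi]

    def dense(self) -> np.ndarray:
        return self.counts.toarray()

    def checksum(self) -> str:
        """SHA-256 over shape, structure and counts (identifies the dataset)."""
        import hashlib

        h = hashlib.sha256()
        h.update(np.asarray(self.counts.shape, dtype=np.int64).tobytes())
        h.update(self.counts.indptr.astype(np.int64).tobytes())
        h.update(self.counts.indices.astype(np.int64).tobytes())
        h.update(self.counts.data.astype(np.int64).tobytes())
        return h.hexdigest()

    def __repr__(self):  # pragma: no cover
        return (
            f"CountMatrix({self.n_genes} genes x {self.n_cells} cells, "
            f"{self.counts.nnz} nonzeros, {self.total_count} UMIs)"
        )


@dataclass
class DirichletPrior:
    """Dirichlet prior over gene expression states.

    Parametrised as a scalar strength ``theta`` times a base measure ``pi``
    on the gene simplex, so the effective concentrations are
    ``theta_g = theta * pi_g`` and their sum is ``theta``.  The Dirichlet
    family is the unique prior family invariant under rescaling of the
    (unobservable) absolute transcription activities, which is why it is the
    natural prior for transcription quotients.
    """

    strength: float
    base_measure: np.ndarray

    def __post_init__(self):
        self.base_measure = np.asarray(self.base_measure, dtype=np.float64)
        if not np.isfinite(self.strength) or self.strength <= 0:
            raise DataError(f"prior strength must be positive, got {self.strength}")
        if np.any(self.base_measure <= 0):
            raise DataError("base measure must be strictly positive")
        if abs(self.base_measure.sum() - 1.0) > 1e-12:
            raise DataError("base measure must sum to 1 (tolerance 1e-12)")

    @property
    def concentrations(self) -> np.ndarray:
        """Per-gene concentrations ``theta_g = theta * pi_g``."""
        return self.strength * self.base_measure

    @property
    def concentration_sum(self) -> float:
        return float(self.strength)

    @property
    def n_genes(self) -> int:
        return self.base_measure.size

    def with_strength(self, strength: float) -> "DirichletPrior":
        return DirichletPrior(strength, self.base_measure)

    @classmethod
    def uniform(cls, n_genes: int, strength: float = 1.0) -> "DirichletPrior":
        return cls(strength, np.full(n_genes, 1.0 / n_genes))

    @classmethod
    def empirical(
        cls, matrix: CountMatrix, strength: float = 1.0, pseudocount: float = 1.0
    ) -> "DirichletPrior":
        """Base measure proportional to dataset-wide gene totals + pseudocount."""
        w = matrix.gene_totals.astype(np.float64) + pseudocount
        return cls(strength, w / w.sum())


@dataclass
class GESEstimate:
    """Posterior-mean transcription quotients of one cluster.

    ``quotients[g] = (n_gs + theta_g) / (N_s + theta)`` -- the mean of the
    Dirichlet posterior over the cluster's GES.
    """

    quotients: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.quotients, dtype=np.float64)
        if np.any(q <= 0):
            raise DataError("GES quotients must be strictly positive")
        if abs(q.sum() - 1.0) > 1e-10:
            raise DataError("GES quotients must sum to 1 (tolerance 1e-10)")
        self.quotients = q

    @classmethod
    def from_counts(cls, counts, total, prior: DirichletPrior) -> "GESEstimate":
        counts = np.asarray(counts, dtype=np.float64)
        return cls((counts + prior.concentrations) / (total + prior.concentration_sum))


class Partition:
    """Assignment of every cell to exactly one non-empty cluster.

    Clusters are internally numbered ``0..K-1``; user-facing labels are kept
    in ``labels``.  Aggregated statistics (``cluster_counts`` = ``n_gs``,
    ``cluster_totals`` = ``N_s``, ``cluster_sizes``) are cached and updated
    incrementally by :func:`move_cell`; they always equal a from-scratch
    recomputation from ``assignment``.
    """

    def __init__(self, matrix: CountMatrix, assignment, cluster_counts,
                 cluster_totals, cluster_sizes, labels):
        self.matrix = matrix
        self.assignment = np.asarray(assignment, dtype=np.int64)
        self.cluster_counts = np.asarray(cluster_counts, dtype=np.int64)
        self.cluster_totals = np.asarray(cluster_totals, dtype=np.int64)
        self.cluster_sizes = np.asarray(cluster_sizes, dtype=np.int64)
        self.labels = list(labels)

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_assignment(cls, matrix: CountMatrix, assignment) -> "Partition":
        """See :func:`build_partition`."""
        return build_partition(matrix, assignment)

    @property
    def n_clusters(self) -> int:
        return len(self.labels)

    @property
    def n_cells(self) -> int:
        return self.assignment.size

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == k)

    def label_of_cell(self, c: int):
        return self.labels[self.assignment[c]]

    def ges(self, k: int, prior: DirichletPrior) -> GESEstimate:
        """Posterior-mean GES of cluster ``k``."""
        return GESEstimate.from_counts(
            self.cluster_counts[k], self.cluster_totals[k], prior
        )

    def copy(self) -> "Partition":
        return Partition(
            self.matrix,
            self.assignment.copy(),
            self.cluster_counts.copy(),
            self.cluster_totals.copy(),
            self.cluster_sizes.copy(),
            list(self.labels),
        )

    def check_consistent(self, atol: int = 0) -> None:
        """Assert cached statistics equal brute-force recomputation."""
        fresh = build_partition(self.matrix, self.assignment)
        if not (
            np.array_equal(fresh.cluster_counts, self.cluster_counts)
            and np.array_equal(fresh.cluster_totals, self.cluster_totals)
            and np.array_equal(fresh.cluster_sizes, self.cluster_sizes)
        ):
            raise AssertionError("cached cluster statistics are inconsistent")

    def __repr__(self):  # pragma: no cover
        return f"Partition({self.n_cells} cells -> {self.n_clusters} clusters)"


def build_partition(matrix: CountMatrix, assignment) -> Partition:
    """Build a :class:`Partition` from a cell -> label mapping.

    ``assignment`` may be a dict keyed by cell index, or a sequence of length
    ``n_cells`` of arbitrary hashable labels.  Labels are renumbered to
    contiguous internal integers (in order of first appearance of the sorted
    unique labels); the original labels are preserved in ``Partition.labels``.
    """
    n = matrix.n_cells
    if isinstance(assignment, dict):
        missing = [c for c in range(n) if c not in assignment]
        if missing:
            raise DataError(f"assignment missing cells: {missing[:10]}")
        if len(assignment) != n:
            extra = [c for c in assignment if not (0 <= c < n)]
            raise DataError(f"assignment refers to unknown cells: {extra[:10]}")
        labels_per_cell = [assignment[c] for c in range(n)]
    else:
        labels_per_cell = list(assignment)
        if len(labels_per_cell) != n:
            raise DataError(
                f"assignment length {len(labels_per_cell)} != n_cells {n}"
            )

    try:
        uniq = sorted(set(labels_per_cell))
    except TypeError:  # mixed unorderable labels
        uniq = list(dict.fromkeys(labels_per_cell))
    index = {lab: i for i, lab in enumerate(uniq)}
    assign = np.array([index[lab] for lab in labels_per_cell], dtype=np.int64)

    k = len(uniq)
    onehot = sp.csr_matrix(
        (np.ones(n), (assign, np.arange(n))), shape=(k, n), dtype=np.int64
    )
    cluster_counts = np.asarray((onehot @ matrix.counts.T).todense(), dtype=np.int64)
    cluster_totals = np.bincount(assign, weights=matrix.cell_totals, minlength=k)
    cluster_sizes = np.bincount(assign, minlength=k)
    return Partition(
        matrix, assign, cluster_counts,
        cluster_totals.astype(np.int64), cluster_sizes.astype(np.int64), uniq,
    )


def singleton_partition(matrix: CountMatrix) -> Partition:
    """The all-singletons partition: each cell is its own cluster.

    This is the optimizer's starting point; cluster statistics equal the
    per-cell counts.
    """
    return build_partition(matrix, np.arange(matrix.n_cells))


def move_cell(partition: Partition, cell: int, target) -> bool:
    """Move ``cell`` into cluster ``target`` (internal index) or ``NEW``.

    Statistics are updated incrementally in O(nnz of the cell).  If the source
    cluster becomes empty it is removed and the last cluster is swapped into
    its slot (a pure relabeling; downstream likelihoods are unaffected).

    Returns ``True`` if the partition changed.  Raises :class:`NoOpMove` when
    the target is the cell's current cluster, and ``IndexError`` for unknown
    cells or clusters.
    """
    n = partition.n_cells
    if not (0 <= cell < n):
        raise IndexError(f"unknown cell {cell}")
    src = int(partition.assignment[cell])
    k = partition.n_clusters

    if target is NEW or (isinstance(target, str) and target == NEW):
        tgt = k
        partition.cluster_counts = np.vstack(
            [partition.cluster_counts, np.zeros((1, partition.matrix.n_genes), dtype=np.int64)]
        )
        partition.cluster_totals = np.append(partition.cluster_totals, 0)
        partition.cluster_sizes = np.append(partition.cluster_sizes, 0)
        new_label = max((l for l in partition.labels if isinstance(l, int)), default=-1) + 1
        partition.labels.append(new_label)
    else:
        tgt = int(target)
        if not (0 <= tgt < k):
            raise IndexError(f"unknown cluster {target}")
        if tgt == src:
            raise NoOpMove(f"cell {cell} already in cluster {target}")

    genes, cnts = partition.matrix.cell_counts(cell)
    nc = int(partition.matrix.cell_totals[cell])
    partition.cluster_counts[src, genes] -= cnts
    partition.cluster_counts[tgt, genes] += cnts
    partition.cluster_totals[src] -= nc
    partition.cluster_totals[tgt] += nc
    partition.cluster_sizes[src] -= 1
    partition.cluster_sizes[tgt] += 1
    partition.assignment[cell] = tgt

    if partition.cluster_sizes[src] == 0:
        last = partition.n_clusters - 1
        if src != last:
            partition.cluster_counts[src] = partition.cluster_counts[last]
            partition.cluster_totals[src] = partition.cluster_totals[last]
            partition.cluster_sizes[src] = partition.cluster_sizes[last]
            partition.labels[src] = partition.labels[last]
            partition.assignment[partition.assignment == last] = src
        partition.cluster_counts = partition.cluster_counts[:last]
        partition.cluster_totals = partition.cluster_totals[:last]
        partition.cluster_sizes = partition.cluster_sizes[:last]
        partition.labels.pop()
    return True
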