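"""Synthetic UMI datasets with a known generating partition.

Datasets are produced exactly as the noise model assumes: each ground-truth
expression state is a point on the gene simplex, each cell is assigned to a
state, and the cell's counts are a multinomial sample of its state's
transcription quotients at the cell's total UMI count.  State abundances are
drawn heavy-tailed so realised cluster sizes span orders of magnitude and
include singlets, mirroring the rank-abundance shape of real tissues; cell
totals are drawn log-normal to emulate library-size spread.

Defaults define the desk-scale benchmark used by the validation suite:
800 cells, 1000 genes, 30 states, median total 2000 UMIs per cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import CountMatrix, DataError, Partition, build_partition

__all__ = ["GroundTruth", "sample_ground_truth", "sample_counts", "downsample"]


@dataclass
class GroundTruth:
    """Generator state: who is in which state, and what the states express.

    state_quotients : (n_states, n_genes) rows on the gene simplex
    state_frequencies : (n_states,) abundances, sum to 1
    cell_assignment : (n_cells,) state index per cell (every state realised)
    cell_totals : (n_cells,) total UMI count per cell
    """

    state_quotients: np.ndarray
    state_frequencies: np.ndarray
    cell_assignment: np.ndarray
    cell_totals: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.state_quotients, dtype=np.float64)
        f = np.asarray(self.state_frequencies, dtype=np.float64)
        if not np.allclose(q.sum(axis=1), 1.0, atol=1e-9):
            raise DataError("state quotients must sum to 1 per state")
        if abs(f.sum() - 1.0) > 1e-9:
            raise DataError("state frequencies must sum to 1")
        realized = np.bincount(self.cell_assignment, minlength=f.size)
        if np.any(realized == 0):
            raise DataError("every state must have at least one cell")
        self.state_quotients = q
        self.state_frequencies = f
        self.cell_assignment = np.asarray(self.cell_assignment, dtype=np.int64)
        self.cell_totals = np.asarray(self.cell_totals, dtype=np.int64)

    @property
    def n_states(self) -> int:
        return self.state_frequencies.size

    @property
    def n_cells(self) -> int:
        return self.cell_assignment.size


def sample_ground_truth(
    n_states: int = 30,
    n_genes: int = 1000,
    n_cells: int = 800,
    concentration: float = 1000.0,
    abundance_shape: str | float = "power",
    abundance_exponent: float = 1.5,
    total_median: float = 2000.0,
    total_sigma: float = 0.6,
    base_concentration: float = 0.5,
    rng: np.random.Generator | int | None = None,
) -> GroundTruth:
    """Draw a ground truth: states, abundances, assignments, cell totals.

    State quotients are Dirichlet draws around a shared heavy-tailed base
    measure (itself a symmetric-Dirichlet draw with ``base_concentration``
    per gene, emulating the orders-of-magnitude spread of real gene
    expression); ``concentration`` is the total Dirichlet concentration, so
    smaller values give more distinct states.  Abundances follow a power law
    ``f_s ~ s^-abundance_exponent`` (``abundance_shape="uniform"`` gives
    equal frequencies).  Unrealised states (possible in the power-law tail)
    are dropped, so every state in the returned truth has at least one cell;
    tail states realised with a single cell are the singlets.
    """
    rng = np.random.default_rng(rng)
    if min(n_states, n_genes, n_cells) < 1:
        raise DataError("n_states, n_genes and n_cells must be positive")
    if concentration <= 0 or total_median <= 0 or total_sigma < 0:
        raise DataError("degenerate generator parameters")
    if n_states > n_cells:
        raise DataError("cannot realise more states than cells")

    base = rng.dirichlet(np.full(n_genes, base_concentration))
    base = np.maximum(base, 1e-12)
    base /= base.sum()
    quotients = rng.dirichlet(concentration * base, size=n_states)
    quotients = np.maximum(quotients, 1e-15)
    quotients /= quotients.sum(axis=1, keepdims=True)

    if abundance_shape == "uniform":
        freqs = np.full(n_states, 1.0 / n_states)
    elif abundance_shape == "power":
        ranks = np.arange(1, n_states + 1, dtype=np.float64)
        freqs = ranks ** (-abundance_exponent)
        freqs /= freqs.sum()
    else:
        raise DataError(f"unknown abundance_shape {abundance_shape!r}")

    # assign cells; unrealised tail states are dropped and renumbered
    assignment = rng.choice(n_states, size=n_cells, p=freqs)
    realized = np.bincount(assignment, minlength=n_states)
    keep = realized > 0
    if not np.all(keep):
        remap = -np.ones(n_states, dtype=np.int64)
        remap[keep] = np.arange(keep.sum())
        assignment = remap[assignment]
        quotients = quotients[keep]
        freqs = freqs[keep] / freqs[keep].sum()

    totals = np.maximum(
        1, np.round(rng.lognormal(np.log(total_median), total_sigma, n_cells))
    ).astype(np.int64)
    return GroundTruth(quotients, freqs, assignment, totals)


def sample_counts(truth: GroundTruth, rng: np.random.Generator | int | None = None):
    """Multinomially sample a count matrix from the truth.

    Cell ``c`` in state ``s`` receives ``Multinomial(alpha_s, N_c)`` counts,
    so per-cell sums equal ``cell_totals`` exactly.  Returns
    ``(CountMatrix, generating Partition)``; the partition is built on the
    returned matrix so its likelihood is directly comparable with inferred
    partitions.
    """
    rng = np.random.default_rng(rng)
    n_cells = truth.n_cells
    counts = np.empty((truth.state_quotients.shape[1], n_cells), dtype=np.int64)
    for s in range(truth.n_states):
        cells = np.flatnonzero(truth.cell_assignment == s)
        draws = rng.multinomial(truth.cell_totals[cells], truth.state_quotients[s])
        counts[:, cells] = draws.T
    matrix = CountMatrix(counts)
    # the matrix may have dropped all-zero genes; the partition is over cells
    partition = build_partition(matrix, truth.cell_assignment)
    return matrix, partition


def downsample(matrix: CountMatrix, fraction: float,
               rng: np.random.Generator | int | None = None) -> CountMatrix:
    """Binomially thin every UMI with retention probability ``fraction``.

    Per-UMI Bernoulli thinning of a multinomial sample is again multinomial
    with the same quotients, so downsampled data stay within the model.
    Cells reduced to zero total are dropped (logged).
    """
    import logging

    if not (0 < fraction <= 1):
        raise DataError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return matrix
    rng = np.random.default_rng(rng)
    thinned = matrix.counts.copy()
    thinned.data = rng.binomial(thinned.data, fraction)
    thinned.eliminate_zeros()
    cell_totals = np.asarray(thinned.sum(axis=0)).ravel()
    keep = cell_totals > 0
    if not np.all(keep):
        logging.getLogger(__name__).info(
            "downsample: dropping %d cells thinned to zero", int((~keep).sum())
        )
    return CountMatrix(
        thinned[:, keep],
        gene_ids=matrix.gene_ids,
        cell_ids=matrix.cell_ids[keep],
    )
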