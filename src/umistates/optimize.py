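"""Search for the maximum-likelihood partition.

The search follows the random-uphill-walk recipe: start from the
all-singletons partition, propose single-cell moves (including moves into a
fresh cluster, so splits stay reachable after merges), accept improvements,
and accept non-improving moves with a Metropolis-Hastings-corrected
probability.  After the chain stops improving, deterministic refinement
applies best single-cell moves and positive pairwise merges to a fixpoint,
and the scalar prior strength theta is re-optimized; the outer loop iterates
to joint convergence.  Multiple independent runs are launched and the
best-scoring partition is kept.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from . import _kernels
from .data import CountMatrix, DirichletPrior, Partition, DataError, \
    build_partition, singleton_partition
from .likelihood import optimize_prior_strength, partition_log_likelihood

logger = logging.getLogger(__name__)

BREAKPOINT_VERSION = 1


@dataclass
class OptimizerConfig:
    """Knobs of the partition search.

    convergence_window
        Consecutive proposals without an accepted improving move after which
        the chain is declared converged; ``None`` means ``20 * n_cells``.
    n_sweeps_max
        Hard cap on MCMC sweeps (one sweep = ``n_cells`` proposals).
    n_runs
        Independent restarts; run ``r`` uses ``seed + r`` and the best final
        likelihood wins.
    theta_reoptimize_every
        If positive, also re-optimize theta every that many sweeps during the
        MCMC phase (it is always re-optimized at phase boundaries).
    uphill_only
        Accept only strictly improving moves (the chain is a pure uphill
        walk; useful for tests of monotonicity).
    """

    n_sweeps_max: int = 1000
    convergence_window: int | None = None
    n_runs: int = 1
    seed: int = 0
    theta_reoptimize_every: int = 0
    allow_new_cluster_proposals: bool = True
    breakpoint_path: str | None = None
    uphill_only: bool = False
    optimize_theta: bool = True
    theta_base: str = "empirical"
    theta_bracket: tuple = (1e-2, 1e7)
    max_outer_rounds: int = 5
    outer_tol: float = 1e-3
    table_kmax: int = 4096

    def __post_init__(self):
        for name in ("n_sweeps_max", "n_runs"):
            if getattr(self, name) < 1:
                raise DataError(f"{name} must be a positive integer")
        if self.convergence_window is not None and self.convergence_window < 1:
            raise DataError("convergence_window must be a positive integer")
        if self.theta_base not in ("uniform", "empirical"):
            raise DataError("theta_base must be 'uniform' or 'empirical'")

    def window_for(self, n_cells: int) -> int:
        return self.convergence_window or 20 * n_cells


@dataclass
class SweepStats:
    proposals: int
    accepted_up: int
    accepted_down: int
    delta_loglik: float


@dataclass
class RunResult:
    """Outcome of one (or the best of several) optimizer runs."""

    partition: Partition
    log_likelihood: float
    prior: DirichletPrior
    trace: np.ndarray
    seed: int
    converged: bool
    n_sweeps: int = 0
    run_logliks: list = field(default_factory=list)

    def check(self):
        """Verify the reported likelihood equals recomputation."""
        ref = partition_log_likelihood(self.partition, self.prior).total_loglik
        if abs(ref - self.log_likelihood) > 1e-6 * max(1.0, abs(ref)):
            raise AssertionError("RunResult likelihood inconsistent")


class SearchState:
    """Mutable array-based search state driving the numba kernels.

    Cluster "slots" are indices ``0..n_cells-1``; occupied slots are listed
    in ``active[:meta[0]]``, empty slots are stacked in ``free[:meta[1]]``
    (lowest slot on top), and ``meta[2]`` counts proposals since the last
    accepted improvement.
    """

    def __init__(self, matrix: CountMatrix, partition: Partition,
                 prior: DirichletPrior, rng: np.random.Generator,
                 table_kmax: int = 4096):
        self.matrix = matrix
        self.rng = rng
        self.table_kmax = table_kmax
        n, G = matrix.n_cells, matrix.n_genes

        self.indptr = matrix.counts.indptr.astype(np.int64)
        self.gidx = matrix.counts.indices.astype(np.int64)
        self.gcnt = matrix.counts.data.astype(np.int64)
        self.cell_tot = matrix.cell_totals

        k = partition.n_clusters
        self.assign = partition.assignment.astype(np.int64).copy()
        self.ccnt = np.zeros((n, G), dtype=np.int64)
        self.ccnt[:k] = partition.cluster_counts
        self.ctot = np.zeros(n, dtype=np.int64)
        self.ctot[:k] = partition.cluster_totals
        self.csize = np.zeros(n, dtype=np.int64)
        self.csize[:k] = partition.cluster_sizes
        self.active = np.zeros(n, dtype=np.int64)
        self.active[:k] = np.arange(k)
        self.apos = np.full(n, -1, dtype=np.int64)
        self.apos[:k] = np.arange(k)
        self.free = np.zeros(n, dtype=np.int64)
        self.free[: n - k] = np.arange(n - 1, k - 1, -1)  # lowest slot on top
        self.meta = np.array([k, n - k, 0], dtype=np.int64)

        self.prior = None
        self.theta = None
        self.table = None
        self.set_prior(prior)
        self.trace: list[float] = []

    # -- prior / likelihood -------------------------------------------------
    def set_prior(self, prior: DirichletPrior) -> None:
        if prior.n_genes != self.matrix.n_genes:
            raise DataError("prior dimension does not match matrix")
        self.prior = prior
        self.theta = prior.concentrations
        kmax = int(min(self.table_kmax, self.matrix.gene_totals.max() + 2))
        kmax = max(kmax, 1)
        self.table = _kernels.build_lgamma_table(self.theta, kmax)
        self.ll = self.loglik_full()

    def loglik_full(self) -> float:
        """Recompute the total log-likelihood from the cluster counts."""
        act = np.sort(self.active[: self.meta[0]])
        sub = self.ccnt[act]
        kk, gg = np.nonzero(sub)
        th = self.theta[gg]
        ts = self.prior.concentration_sum
        val = act.size * gammaln(ts) - float(np.sum(gammaln(ts + self.ctot[act])))
        val += float(np.sum(gammaln(th + sub[kk, gg]) - gammaln(th)))
        return float(val)

    @property
    def n_clusters(self) -> int:
        return int(self.meta[0])

    # -- moves --------------------------------------------------------------
    def sweep(self, n_proposals: int | None = None, *, uphill_only=False,
              allow_new=True, window: int | None = None) -> SweepStats:
        """Run one MCMC sweep (default ``n_cells`` proposals)."""
        n = n_proposals or self.matrix.n_cells
        window = window if window is not None else 1 << 62
        u = self.rng.random((3, n))
        done, up, down, dll = _kernels.run_proposals(
            self.indptr, self.gidx, self.gcnt, self.cell_tot, self.assign,
            self.ccnt, self.ctot, self.csize, self.active, self.apos,
            self.free, self.meta, self.theta,
            self.prior.concentration_sum, self.table,
            u[0], u[1], u[2], allow_new, uphill_only, window,
        )
        self.ll += dll
        return SweepStats(int(done), int(up), int(down), float(dll))

    def refine(self) -> int:
        """Deterministic refinement to a local optimum (single-cell best
        moves, then positive pairwise merges, repeated to a fixpoint)."""
        total = 0
        while True:
            moves, dll = _kernels.refine_cells_pass(
                self.indptr, self.gidx, self.gcnt, self.cell_tot, self.assign,
                self.ccnt, self.ctot, self.csize, self.active, self.apos,
                self.free, self.meta, self.theta,
                self.prior.concentration_sum, self.table,
            )
            self.ll += dll
            merges, dll = _kernels.merge_clusters_pass(
                self.assign, self.ccnt, self.ctot, self.csize, self.active,
                self.apos, self.free, self.meta, self.theta,
                self.prior.concentration_sum, self.table,
            )
            self.ll += dll
            total += moves + merges
            if moves + merges == 0:
                return total

    def reoptimize_theta(self, base_measure, bracket=(1e-2, 1e7)) -> float:
        part = self.to_partition()
        theta, ll = optimize_prior_strength(part, base_measure, bracket)
        self.set_prior(DirichletPrior(theta, base_measure))
        return theta

    # -- conversion / persistence ------------------------------------------
    def to_partition(self) -> Partition:
        """Materialise the current assignment as a consistent Partition
        (statistics rebuilt from scratch; slots renumbered ascending)."""
        act = np.sort(self.active[: self.meta[0]])
        rank = np.zeros(self.assign.size, dtype=np.int64)
        rank[act] = np.arange(act.size)
        return build_partition(self.matrix, rank[self.assign])

    def save(self, path) -> None:
        """Write a breakpoint: slot-exact assignment, prior, rng state and
        trace, plus a checksum of the matrix; restorable bit-exactly (a
        resumed run reproduces an uninterrupted one on the same seed
        stream)."""
        state_json = json.dumps(
            {
                "version": BREAKPOINT_VERSION,
                "rng_state": self.rng.bit_generator.state,
                "checksum": self.matrix.checksum(),
                "theta_strength": self.prior.strength,
            }
        )
        np.savez(
            path,
            meta_json=np.array(state_json),
            assignment=self.assign,
            active=self.active,
            free=self.free,
            counters=self.meta,
            base_measure=self.prior.base_measure,
            trace=np.asarray(self.trace, dtype=np.float64),
        )

    @classmethod
    def load(cls, path, matrix: CountMatrix, table_kmax: int = 4096
             ) -> "SearchState":
        with np.load(path, allow_pickle=False) as fh:
            meta = json.loads(str(fh["meta_json"]))
            if meta.get("version") != BREAKPOINT_VERSION:
                raise DataError(
                    f"breakpoint version {meta.get('version')} != "
                    f"{BREAKPOINT_VERSION}"
                )
            if meta["checksum"] != matrix.checksum():
                raise DataError("breakpoint was written for a different matrix")
            assignment = fh["assignment"]
            active = fh["active"]
            free = fh["free"]
            counters = fh["counters"]
            base = fh["base_measure"]
            trace = list(fh["trace"])
        prior = DirichletPrior(meta["theta_strength"], base)
        rng = np.random.default_rng()
        rng.bit_generator.state = meta["rng_state"]
        st = cls(matrix, singleton_partition(matrix), prior, rng, table_kmax)
        # restore the exact slot layout (cluster statistics rebuilt per slot)
        n, G = matrix.n_cells, matrix.n_genes
        st.assign = assignment.astype(np.int64)
        st.ccnt = np.zeros((n, G), dtype=np.int64)
        np.add.at(st.ccnt, st.assign, matrix.counts.toarray().T)
        st.ctot = np.bincount(st.assign, weights=matrix.cell_totals,
                              minlength=n).astype(np.int64)
        st.csize = np.bincount(st.assign, minlength=n).astype(np.int64)
        st.active = active.astype(np.int64)
        st.free = free.astype(np.int64)
        st.meta = counters.astype(np.int64)
        st.apos = np.full(n, -1, dtype=np.int64)
        for pos in range(int(st.meta[0])):
            st.apos[st.active[pos]] = pos
        st.ll = st.loglik_full()
        st.trace = trace
        return st


def mcmc_sweep(state: SearchState, *, uphill_only=False, allow_new=True
               ) -> SweepStats:
    """One sweep of ``n_cells`` random single-cell move proposals."""
    return state.sweep(uphill_only=uphill_only, allow_new=allow_new)


def deterministic_refine(state: SearchState) -> SearchState:
    """Refine ``state`` in place to a local optimum and return it."""
    state.refine()
    return state


def save_breakpoint(state: SearchState, path) -> None:
    state.save(path)


def load_breakpoint(path, matrix: CountMatrix) -> SearchState:
    return SearchState.load(path, matrix)


def _base_measure(matrix: CountMatrix, config: OptimizerConfig) -> np.ndarray:
    if config.theta_base == "uniform":
        return np.full(matrix.n_genes, 1.0 / matrix.n_genes)
    return DirichletPrior.empirical(matrix).base_measure


def _single_run(matrix, config, run_seed, initial_partition=None,
                prior=None, state=None) -> RunResult:
    window = config.window_for(matrix.n_cells)
    if state is None:
        rng = np.random.default_rng(run_seed)
        part0 = initial_partition or singleton_partition(matrix)
        if prior is None:
            base = _base_measure(matrix, config)
            if config.optimize_theta:
                theta0, _ = optimize_prior_strength(
                    part0, base, config.theta_bracket
                )
            else:
                theta0 = 1.0
            prior = DirichletPrior(theta0, base)
        state = SearchState(matrix, part0, prior, rng, config.table_kmax)

    base = state.prior.base_measure
    n_sweeps = 0
    converged = False
    ll_prev = -np.inf
    for rnd in range(config.max_outer_rounds):
        state.meta[2] = 0
        converged = False
        while n_sweeps < config.n_sweeps_max:
            stats = state.sweep(
                uphill_only=config.uphill_only,
                allow_new=config.allow_new_cluster_proposals,
                window=window,
            )
            n_sweeps += 1
            state.trace.append(state.ll)
            if (
                config.theta_reoptimize_every
                and n_sweeps % config.theta_reoptimize_every == 0
                and config.optimize_theta
            ):
                state.reoptimize_theta(base, config.theta_bracket)
            if state.meta[2] >= window:
                converged = True
                break
        state.refine()
        if config.optimize_theta:
            state.reoptimize_theta(base, config.theta_bracket)
        else:
            state.ll = state.loglik_full()
        state.trace.append(state.ll)
        if state.ll - ll_prev < config.outer_tol:
            break
        ll_prev = state.ll
        if config.breakpoint_path:
            state.save(config.breakpoint_path)

    part = state.to_partition()
    state.ll = state.loglik_full()
    return RunResult(
        partition=part,
        log_likelihood=state.ll,
        prior=state.prior,
        trace=np.asarray(state.trace),
        seed=run_seed,
        converged=converged,
        n_sweeps=n_sweeps,
    )


def run(matrix: CountMatrix, config: OptimizerConfig | None = None,
        initial_partition: Partition | None = None,
        prior: DirichletPrior | None = None) -> RunResult:
    """Best-of-``n_runs`` partition search.

    Each run is independently seeded (``config.seed + r``), starts from the
    all-singletons partition (or ``initial_partition``), and follows the
    MCMC -> refine -> theta-reoptimization outer loop.  The run with the
    highest final log-likelihood is returned; all runs' summaries are
    logged, and their likelihoods are kept in ``RunResult.run_logliks``.
    """
    config = config or OptimizerConfig()
    results = []
    for r in range(config.n_runs):
        res = _single_run(matrix, config, config.seed + r,
                          initial_partition=initial_partition, prior=prior)
        logger.info(
            "run %d: loglik=%.3f clusters=%d sweeps=%d converged=%s",
            r, res.log_likelihood, res.partition.n_clusters, res.n_sweeps,
            res.converged,
        )
        results.append(res)
    best = max(results, key=lambda r: r.log_likelihood)
    best.run_logliks = [r.log_likelihood for r in results]
    return best


def run_incremental(matrix_new_cells: CountMatrix, prior_result: RunResult,
                    config: OptimizerConfig | None = None) -> RunResult:
    """Extend an existing partition with new cells and re-optimize jointly.

    The new cells start as singletons next to the previous partition; the
    gene universes are reconciled by intersection (mismatches logged, empty
    intersection is an error).  The returned likelihood is never below that
    of the naive union (old partition + new singletons) at the final prior.
    """
    config = config or OptimizerConfig()
    old = prior_result.partition.matrix
    old_genes = {g: i for i, g in enumerate(old.gene_ids)}
    shared = [g for g in matrix_new_cells.gene_ids if g in old_genes] \
        if matrix_new_cells.n_cells else list(old.gene_ids)
    if matrix_new_cells.n_cells and not shared:
        raise DataError("no genes in common between old and new cells")
    if matrix_new_cells.n_cells and (
        len(shared) < old.n_genes or len(shared) < matrix_new_cells.n_genes
    ):
        logger.warning(
            "gene universes differ; keeping %d shared genes", len(shared)
        )

    if matrix_new_cells.n_cells == 0:
        combined = old
        init_labels = [prior_result.partition.labels[k]
                       for k in prior_result.partition.assignment]
    else:
        old_idx = [old_genes[g] for g in shared]
        new_pos = {g: i for i, g in enumerate(matrix_new_cells.gene_ids)}
        new_idx = [new_pos[g] for g in shared]
        import scipy.sparse as sp

        block = sp.hstack(
            [old.counts[old_idx, :], matrix_new_cells.counts[new_idx, :]]
        )
        old_ids = [str(c) for c in old.cell_ids]
        new_ids = [str(c) for c in matrix_new_cells.cell_ids]
        if set(old_ids) & set(new_ids):
            logger.warning("new cell ids collide with old ones; suffixing #new")
            new_ids = [f"{c}#new" for c in new_ids]
        combined = CountMatrix(block, gene_ids=shared,
                               cell_ids=old_ids + new_ids)
        init_labels = [("old", int(k)) for k in prior_result.partition.assignment]
        init_labels += [("new", c) for c in range(matrix_new_cells.n_cells)]

    init = build_partition(combined, init_labels)
    res = run(combined, config, initial_partition=init)
    baseline = partition_log_likelihood(init, res.prior).total_loglik
    if res.log_likelihood < baseline:
        res = RunResult(
            partition=init, log_likelihood=baseline, prior=res.prior,
            trace=res.trace, seed=res.seed, converged=res.converged,
            n_sweeps=res.n_sweeps, run_logliks=res.run_logliks,
        )
    return res
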