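import numpy as np
import pytest

from umistates.data import (
    CountMatrix,
    DataError,
    DirichletPrior,
    build_partition,
    singleton_partition,
)
from umistates.likelihood import (
    delta_move,
    pair_merge_log_ratio,
    partition_log_likelihood,
)
from umistates.optimize import (
    OptimizerConfig,
    SearchState,
    deterministic_refine,
    load_breakpoint,
    run,
    run_incremental,
    save_breakpoint,
)
from umistates import simulate

from conftest import random_matrix


def two_state_matrix():
    cols = [[100, 0]] * 5 + [[0, 100]] * 5
    return CountMatrix(np.array(cols).T)


@pytest.fixture
def unit2():
    return DirichletPrior.uniform(2, 2.0)


class TestSearchState:
    def test_incremental_loglik_matches_full(self, rng, unit2):
        m = random_matrix(rng, n_genes=2, n_cells=20, mean_total=40)
        st = SearchState(m, singleton_partition(m), unit2, np.random.default_rng(0))
        for _ in range(20):
            st.sweep()
        assert st.ll == pytest.approx(st.loglik_full(), rel=1e-10, abs=1e-7)
        part = st.to_partition()
        assert partition_log_likelihood(part, unit2).total_loglik == pytest.approx(
            st.ll, rel=1e-10, abs=1e-7
        )

    def test_kernel_deltas_agree_with_reference(self, rng):
        # drive the chain, then compare its likelihood against the pure
        # numpy/scipy recomputation path at several checkpoints
        m = random_matrix(rng, n_genes=8, n_cells=30, mean_total=50)
        prior = DirichletPrior.empirical(m, 25.0)
        st = SearchState(m, singleton_partition(m), prior, np.random.default_rng(3))
        for _ in range(10):
            st.sweep()
            ref = partition_log_likelihood(st.to_partition(), prior).total_loglik
            assert st.ll == pytest.approx(ref, rel=1e-9, abs=1e-6)

    def test_uphill_only_trace_is_nondecreasing(self, rng, unit2):
        m = random_matrix(rng, n_genes=2, n_cells=25, mean_total=30)
        st = SearchState(m, singleton_partition(m), unit2, np.random.default_rng(5))
        lls = [st.ll]
        for _ in range(30):
            st.sweep(uphill_only=True)
            lls.append(st.ll)
        assert np.all(np.diff(lls) >= -1e-9)


class TestMCMC:
    def test_identical_cells_collapse_to_one_cluster(self, unit2):
        m = CountMatrix(np.tile([[50], [50]], (1, 10)))
        res = run(m, OptimizerConfig(seed=1, optimize_theta=False), prior=unit2)
        assert res.partition.n_clusters == 1

    def test_two_separated_states_found_exactly(self, unit2):
        m = two_state_matrix()
        res = run(
            m, OptimizerConfig(seed=4, n_runs=3, optimize_theta=False), prior=unit2
        )
        assert res.partition.n_clusters == 2
        assert len(set(res.partition.assignment[:5])) == 1
        assert len(set(res.partition.assignment[5:])) == 1
        # local optimality: no single-cell move improves
        p = res.partition
        led = partition_log_likelihood(p, unit2)
        for c in range(10):
            for t in range(p.n_clusters):
                if t != p.assignment[c]:
                    assert delta_move(led, p, unit2, c, t) <= 1e-9
        assert pair_merge_log_ratio(p, unit2, 0, 1) < 0

    def test_same_seed_is_deterministic(self, rng):
        m = random_matrix(rng, n_genes=10, n_cells=40, mean_total=80)
        cfg = OptimizerConfig(seed=9, n_runs=2)
        r1 = run(m, cfg)
        r2 = run(m, cfg)
        assert np.array_equal(r1.partition.assignment, r2.partition.assignment)
        assert r1.log_likelihood == r2.log_likelihood

    def test_best_of_runs_is_max(self, rng):
        m = random_matrix(rng, n_genes=10, n_cells=30, mean_total=60)
        res = run(m, OptimizerConfig(seed=0, n_runs=4))
        assert res.log_likelihood == max(res.run_logliks)
        res.check()


class TestDeterministicRefine:
    def test_fixpoint_left_unchanged(self, unit2):
        m = two_state_matrix()
        p = build_partition(m, [0] * 5 + [1] * 5)
        st = SearchState(m, p, unit2, np.random.default_rng(0))
        moved = st.refine()
        assert moved == 0
        assert np.array_equal(np.sort(st.to_partition().cluster_sizes), [5, 5])

    def test_monotone_and_reaches_two_states(self, rng, unit2):
        m = two_state_matrix()
        p = build_partition(m, rng.integers(0, 4, 10))
        st = SearchState(m, p, unit2, np.random.default_rng(0))
        ll0 = st.ll
        deterministic_refine(st)
        assert st.ll >= ll0 - 1e-9
        part = st.to_partition()
        assert part.n_clusters == 2
        # confirmed local optimum: every single-move neighbour is worse
        led = partition_log_likelihood(part, unit2)
        for c in range(10):
            for t in range(part.n_clusters):
                if t != part.assignment[c]:
                    assert delta_move(led, part, unit2, c, t) <= 1e-9


class TestBreakpoints:
    def test_round_trip_preserves_ledger(self, rng, tmp_path, unit2):
        m = random_matrix(rng, n_genes=2, n_cells=15)
        st = SearchState(m, singleton_partition(m), unit2, np.random.default_rng(2))
        for _ in range(5):
            st.sweep()
        save_breakpoint(st, tmp_path / "bp.npz")
        st2 = load_breakpoint(tmp_path / "bp.npz", m)
        assert st2.ll == pytest.approx(st.ll, rel=1e-12)
        assert np.array_equal(
            st.to_partition().assignment, st2.to_partition().assignment
        )

    def test_resume_equals_uninterrupted(self, rng, tmp_path, unit2):
        m = random_matrix(rng, n_genes=3, n_cells=20, mean_total=40)
        prior = DirichletPrior.uniform(3, 3.0)
        a = SearchState(m, singleton_partition(m), prior, np.random.default_rng(11))
        for _ in range(20):
            a.sweep()

        b = SearchState(m, singleton_partition(m), prior, np.random.default_rng(11))
        for _ in range(10):
            b.sweep()
        b.save(tmp_path / "bp.npz")
        c = SearchState.load(tmp_path / "bp.npz", m)
        for _ in range(10):
            c.sweep()
        assert np.array_equal(a.to_partition().assignment, c.to_partition().assignment)
        assert a.ll == pytest.approx(c.ll, rel=1e-12)

    def test_loading_onto_other_matrix_fails(self, rng, tmp_path, unit2):
        m1 = random_matrix(rng, n_genes=2, n_cells=10)
        m2 = random_matrix(rng, n_genes=2, n_cells=10)
        st = SearchState(m1, singleton_partition(m1), unit2, np.random.default_rng(0))
        st.save(tmp_path / "bp.npz")
        with pytest.raises(DataError, match="different matrix"):
            SearchState.load(tmp_path / "bp.npz", m2)


@pytest.fixture(scope="module")
def fitted():
    truth = simulate.sample_ground_truth(
        n_states=5, n_genes=120, n_cells=120, total_median=600,
        abundance_shape="uniform", rng=21,
    )
    m, gen = simulate.sample_counts(truth, np.random.default_rng(22))
    res = run(m, OptimizerConfig(seed=5))
    return truth, m, gen, res


class TestIncremental:
    def test_zero_new_cells_not_worse(self, fitted):
        import scipy.sparse as sp

        _, m, _, res = fitted
        empty = CountMatrix(
            sp.csc_matrix((m.n_genes, 0), dtype=np.int64),
            gene_ids=m.gene_ids, cell_ids=[],
        )
        out = run_incremental(empty, res, OptimizerConfig(seed=6))
        assert out.log_likelihood >= res.log_likelihood - 1e-6

    def test_new_cells_absorbed_into_matching_state(self, fitted):
        truth, m, gen, res = fitted
        # 5 extra cells sampled from ground-truth state 0
        rng = np.random.default_rng(33)
        extra = np.column_stack(
            [rng.multinomial(600, truth.state_quotients[0]) for _ in range(5)]
        )
        full_gene_ids = [f"g{i}" for i in range(extra.shape[0])]
        new = CountMatrix(extra, cell_ids=[f"x{i}" for i in range(5)],
                          gene_ids=full_gene_ids, drop_zero_genes=False)
        out = run_incremental(new, res, OptimizerConfig(seed=7))
        assign = out.partition.assignment
        new_idx = np.arange(m.n_cells, m.n_cells + 5)
        host = assign[gen.members(0)]
        # all new cells join the cluster hosting state 0's cells
        assert set(assign[new_idx]) <= set(host)

    def test_split_halves_close_to_joint_run(self, fitted):
        truth, m, gen, res_joint = fitted
        half = m.n_cells // 2
        m1 = CountMatrix(m.counts[:, :half], gene_ids=m.gene_ids,
                         cell_ids=m.cell_ids[:half])
        m2 = CountMatrix(m.counts[:, half:], gene_ids=m.gene_ids,
                         cell_ids=m.cell_ids[half:])
        first = run(m1, OptimizerConfig(seed=8))
        combined = run_incremental(m2, first, OptimizerConfig(seed=9))
        from umistates.evaluation import homogeneity_completeness

        joint = homogeneity_completeness(res_joint.partition.assignment,
                                         gen.assignment)
        incr = homogeneity_completeness(combined.partition.assignment,
                                        gen.assignment)
        assert abs(joint.homogeneity - incr.homogeneity) <= 0.05
        assert abs(joint.completeness - incr.completeness) <= 0.05


def test_recovery_on_well_separated_simulation():
    # generating states pairwise separated by large negative merge ratios:
    # the search recovers the truth exactly
    truth = simulate.sample_ground_truth(
        n_states=6, n_genes=150, n_cells=150, total_median=1000,
        abundance_shape="uniform", rng=40,
    )
    m, gen = simulate.sample_counts(truth, np.random.default_rng(41))
    res = run(m, OptimizerConfig(seed=10))
    worst = max(
        pair_merge_log_ratio(gen, res.prior, a, b)
        for a in range(gen.n_clusters)
        for b in range(a + 1, gen.n_clusters)
    )
    assert worst < -20
    from umistates.evaluation import homogeneity_completeness

    rep = homogeneity_completeness(res.partition, gen)
    assert rep.homogeneity == 1.0 and rep.completeness == 1.0
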