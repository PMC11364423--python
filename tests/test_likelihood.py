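import numpy as np
import pytest
from scipy import integrate
from scipy.special import gammaln

from umistates.data import (
    NEW,
    CountMatrix,
    DataError,
    DirichletPrior,
    build_partition,
    move_cell,
    singleton_partition,
)
from umistates.likelihood import (
    cluster_log_marginal,
    delta_move,
    optimize_prior_strength,
    pair_merge_log_ratio,
    partition_log_likelihood,
)

from conftest import random_matrix


def dirichlet_multinomial_quadrature(counts, theta):
    """Brute-force integral of prod_g alpha_g^n_g against Dir(theta) on the
    simplex (G = 2 or 3): the independent oracle for the analytic marginal."""
    counts = np.asarray(counts, dtype=float)
    theta = np.asarray(theta, dtype=float)
    norm = gammaln(theta.sum()) - gammaln(theta).sum()

    if len(theta) == 2:
        def f(a1):
            return np.exp(
                (theta[0] - 1 + counts[0]) * np.log(a1)
                + (theta[1] - 1 + counts[1]) * np.log1p(-a1)
            )
        val, _ = integrate.quad(f, 0, 1, epsabs=1e-13, epsrel=1e-12)
    else:
        def f(a2, a1):
            a3 = 1.0 - a1 - a2
            if a3 <= 0:
                return 0.0
            return np.exp(
                (theta[0] - 1 + counts[0]) * np.log(a1)
                + (theta[1] - 1 + counts[1]) * np.log(a2)
                + (theta[2] - 1 + counts[2]) * np.log(a3)
            )
        val, _ = integrate.dblquad(
            f, 0, 1, 0, lambda a1: 1 - a1, epsabs=1e-12, epsrel=1e-10
        )
    return np.exp(norm) * val


class TestClusterLogMarginal:
    def test_beta_integral_closed_forms(self, unit_prior):
        # theta = (1,1): int_0^1 a^n da = 1/(n+1)
        assert cluster_log_marginal([1, 0], 1, unit_prior) == pytest.approx(np.log(1 / 2))
        assert cluster_log_marginal([2, 0], 2, unit_prior) == pytest.approx(np.log(1 / 3))

    def test_empty_cluster_contributes_nothing(self, unit_prior):
        assert cluster_log_marginal([0, 0], 0, unit_prior) == 0.0

    @pytest.mark.parametrize(
        "counts,theta",
        [
            ([2, 1, 0], [0.5, 0.5, 0.5]),
            ([3, 2, 1], [1.0, 2.0, 0.7]),
            ([0, 4, 2], [0.2, 1.5, 3.0]),
            ([5, 1], [0.3, 0.9]),
            ([6, 0], [2.0, 2.0]),
        ],
    )
    def test_matches_simplex_quadrature(self, counts, theta):
        theta = np.asarray(theta, dtype=float)
        prior = DirichletPrior(theta.sum(), theta / theta.sum())
        expected = np.log(dirichlet_multinomial_quadrature(counts, theta))
        got = cluster_log_marginal(counts, sum(counts), prior)
        assert got == pytest.approx(expected, abs=1e-6)

    def test_nonzero_restriction_is_exact(self):
        theta = np.array([0.5, 1.0, 2.0, 0.1])
        prior = DirichletPrior(theta.sum(), theta / theta.sum())
        sparse = cluster_log_marginal([5, 0, 3, 0], 8, prior)
        # padding with zero-count genes must not change the value
        theta2 = np.concatenate([theta, [0.4, 0.6]])
        prior2 = DirichletPrior(theta2.sum(), theta2 / theta2.sum())
        # different prior dimension => different theta_sum; instead compare
        # against the explicit full sum with the same prior
        full = (
            gammaln(prior.concentration_sum)
            - gammaln(prior.concentration_sum + 8)
            + sum(
                gammaln(prior.concentrations[g] + n) - gammaln(prior.concentrations[g])
                for g, n in enumerate([5, 0, 3, 0])
            )
        )
        assert sparse == pytest.approx(full, abs=1e-12)

    def test_invalid_inputs(self, unit_prior):
        with pytest.raises(DataError):
            cluster_log_marginal([-1, 1], 0, unit_prior)
        with pytest.raises(DataError):
            cluster_log_marginal([1.5, 0], 1.5, unit_prior)
        with pytest.raises(DataError):
            cluster_log_marginal([1, 0], 5, unit_prior)


class TestPartitionLogLikelihood:
    def test_single_cluster_equals_grand_total(self, rng):
        m = random_matrix(rng, n_genes=4, n_cells=8)
        prior = DirichletPrior.uniform(4, 1.5)
        led = partition_log_likelihood(build_partition(m, [0] * 8), prior)
        grand = cluster_log_marginal(m.dense().sum(axis=1), None, prior)
        assert led.total_loglik == pytest.approx(grand, abs=1e-12)

    def test_ledger_total_is_sum_of_terms(self, rng):
        m = random_matrix(rng, n_genes=4, n_cells=9)
        prior = DirichletPrior.uniform(4, 1.5)
        led = partition_log_likelihood(build_partition(m, [0, 0, 0, 1, 1, 1, 2, 2, 2]), prior)
        assert led.total_loglik == pytest.approx(sum(led.per_cluster_loglik.values()))
        led.check(build_partition(m, [0, 0, 0, 1, 1, 1, 2, 2, 2]))

    def test_two_gene_worked_fixture(self, unit_prior):
        # cells (1,0), (1,0): singletons (1/2)^2, merged 1/3
        m = CountMatrix([[1, 1], [0, 0]], drop_zero_genes=False)
        singles = partition_log_likelihood(singleton_partition(m), unit_prior)
        merged = partition_log_likelihood(build_partition(m, [0, 0]), unit_prior)
        assert singles.total_loglik == pytest.approx(2 * np.log(1 / 2))
        assert merged.total_loglik == pytest.approx(np.log(1 / 3))

    def test_gene_permutation_invariance(self, rng):
        m = random_matrix(rng, n_genes=5, n_cells=10)
        theta = np.array([0.3, 0.9, 1.1, 0.2, 0.5])
        labels = rng.integers(0, 3, 10)
        perm = rng.permutation(5)
        m2 = CountMatrix(m.dense()[perm], drop_zero_genes=False)
        l1 = partition_log_likelihood(
            build_partition(m, labels), DirichletPrior(theta.sum(), theta / theta.sum())
        ).total_loglik
        l2 = partition_log_likelihood(
            build_partition(m2, labels),
            DirichletPrior(theta.sum(), theta[perm] / theta.sum()),
        ).total_loglik
        assert l1 == pytest.approx(l2, abs=1e-9)

    def test_ratios_unaffected_by_multinomial_coefficients(self, rng):
        # the dropped per-cell coefficients are partition-independent: adding
        # them shifts every partition's loglik by the same constant
        m = random_matrix(rng, n_genes=3, n_cells=6)
        prior = DirichletPrior.uniform(3, 1.0)
        coeff = sum(
            gammaln(m.cell_totals[c] + 1) - gammaln(m.cell_counts(c)[1] + 1).sum()
            for c in range(6)
        )
        partitions = [[0] * 6, [0, 0, 0, 1, 1, 1], list(range(6)), [0, 1, 0, 1, 0, 1]]
        lls = [
            partition_log_likelihood(build_partition(m, p), prior).total_loglik
            for p in partitions
        ]
        lls_with = [ll + coeff for ll in lls]
        for i in range(len(lls)):
            for j in range(len(lls)):
                assert lls[i] - lls[j] == pytest.approx(
                    lls_with[i] - lls_with[j], abs=1e-9
                )


class TestDeltaMove:
    def test_like_cells_attract(self, unit_prior):
        m = CountMatrix([[1, 1], [0, 0]], drop_zero_genes=False)
        p = singleton_partition(m)
        led = partition_log_likelihood(p, unit_prior)
        assert delta_move(led, p, unit_prior, 1, 0) == pytest.approx(np.log(4 / 3))

    def test_unlike_cells_repel(self, unit_prior):
        m = CountMatrix([[1, 0], [0, 1]])
        p = singleton_partition(m)
        led = partition_log_likelihood(p, unit_prior)
        assert delta_move(led, p, unit_prior, 1, 0) == pytest.approx(np.log(2 / 3))

    def test_antisymmetry_of_reverse_move(self, rng):
        m = random_matrix(rng, n_genes=5, n_cells=10)
        prior = DirichletPrior.empirical(m, 3.0)
        p = build_partition(m, [0, 0, 0, 0, 1, 1, 1, 2, 2, 2])
        led = partition_log_likelihood(p, prior)
        fwd = delta_move(led, p, prior, 0, 1)
        move_cell(p, 0, 1)
        led2 = partition_log_likelihood(p, prior)
        back = delta_move(led2, p, prior, 0, 0)
        assert fwd == pytest.approx(-back, abs=1e-10)

    def test_matches_full_recomputation_on_random_moves(self, rng):
        m = random_matrix(rng, n_genes=6, n_cells=15)
        prior = DirichletPrior.empirical(m, 10.0)
        p = build_partition(m, rng.integers(0, 4, 15))
        for _ in range(200):
            led = partition_log_likelihood(p, prior)
            c = int(rng.integers(15))
            src = p.assignment[c]
            if rng.random() < 0.2 and p.cluster_sizes[src] > 1:
                tgt = NEW
            else:
                opts = [k for k in range(p.n_clusters) if k != src]
                tgt = opts[rng.integers(len(opts))]
            d = delta_move(led, p, prior, c, tgt)
            before = led.total_loglik
            move_cell(p, c, tgt)
            after = partition_log_likelihood(p, prior).total_loglik
            assert d == pytest.approx(after - before, rel=1e-8, abs=1e-8)


class TestPairMergeLogRatio:
    def test_identical_singlet_clusters(self, unit_prior):
        m = CountMatrix([[1, 1], [0, 0]], drop_zero_genes=False)
        p = singleton_partition(m)
        assert pair_merge_log_ratio(p, unit_prior, 0, 1) == pytest.approx(np.log(4 / 3))

    def test_symmetry_is_bit_identical(self, rng):
        m = random_matrix(rng, n_genes=5, n_cells=10)
        prior = DirichletPrior.empirical(m, 5.0)
        p = build_partition(m, [0, 0, 0, 1, 1, 1, 2, 2, 2, 2])
        assert pair_merge_log_ratio(p, prior, 0, 2) == pair_merge_log_ratio(p, prior, 2, 0)

    def test_identical_arguments_rejected(self, rng):
        m = random_matrix(rng)
        p = build_partition(m, [0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1])
        with pytest.raises(DataError):
            pair_merge_log_ratio(p, DirichletPrior.uniform(m.n_genes), 1, 1)

    def test_equals_summed_move_deltas(self, rng):
        # merging b into a by moving every member equals the pair ratio
        m = random_matrix(rng, n_genes=5, n_cells=12)
        prior = DirichletPrior.empirical(m, 8.0)
        p = build_partition(m, [0] * 6 + [1] * 6)
        ratio = pair_merge_log_ratio(p, prior, 0, 1)
        total = 0.0
        for cell in list(p.members(1)):
            led = partition_log_likelihood(p, prior)
            total += delta_move(led, p, prior, cell, 0)
            move_cell(p, cell, 0)
        assert total == pytest.approx(ratio, rel=1e-10, abs=1e-10)


class TestOptimizePriorStrength:
    def test_beats_bracket_endpoints(self, rng):
        m = random_matrix(rng, n_genes=8, n_cells=30, mean_total=100)
        p = build_partition(m, rng.integers(0, 5, 30))
        base = DirichletPrior.empirical(m).base_measure
        theta, ll = optimize_prior_strength(p, base, bracket=(0.1, 1e5))
        for edge in (0.1, 1e5):
            ll_edge = sum(
                cluster_log_marginal(p.cluster_counts[k], None, DirichletPrior(edge, base))
                for k in range(p.n_clusters)
            )
            assert ll >= ll_edge - 1e-9

    def test_matches_dense_grid_scan(self, rng):
        m = random_matrix(rng, n_genes=6, n_cells=25, mean_total=60)
        p = build_partition(m, rng.integers(0, 4, 25))
        base = DirichletPrior.empirical(m).base_measure
        theta, ll = optimize_prior_strength(p, base, bracket=(0.1, 1e5))
        grid = np.logspace(-1, 5, 50)
        lls = [
            sum(
                cluster_log_marginal(p.cluster_counts[k], None, DirichletPrior(t, base))
                for k in range(p.n_clusters)
            )
            for t in grid
        ]
        assert ll >= max(lls) - 1e-6

    def test_recovers_generating_strength_within_factor_two(self):
        # states drawn from Dir(theta_true * base): with many clusters the
        # fitted scalar strength should land near the truth
        rng = np.random.default_rng(7)
        n_genes, n_states, cells_per = 100, 50, 10
        theta_true = 200.0
        base = np.full(n_genes, 1.0 / n_genes)
        quot = rng.dirichlet(theta_true * base, size=n_states)
        counts = np.column_stack(
            [
                rng.multinomial(500, quot[s])
                for s in range(n_states)
                for _ in range(cells_per)
            ]
        )
        m = CountMatrix(counts, drop_zero_genes=False)
        labels = np.repeat(np.arange(n_states), cells_per)
        p = build_partition(m, labels)
        theta, _ = optimize_prior_strength(p, base, bracket=(1.0, 1e6))
        assert theta_true / 2 <= theta <= theta_true * 2
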