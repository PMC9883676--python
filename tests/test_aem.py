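"""Alternating EM: initialization, updates, convergence and recovery."""

import numpy as np
import pytest

import aemquant as aq
from aemquant.aem import (
    AbundanceMatrix,
    ConvergenceCriterion,
    CountMatrix,
    aem_fit,
    beta_update,
    build_count_matrix,
    converged,
    init_beta,
    poisson_deviance,
    x_update,
)

from conftest import poisson_counts


def diagonal_system(y):
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    T = y.shape[0]
    X = aq.DesignMatrix(
        [f"t{i}" for i in range(T)],
        [tuple(int(i == j) for j in range(T)) for i in range(T)],
        np.eye(T),
    )
    return X, CountMatrix(X.patterns, y)


class TestInitBeta:
    def test_all_zero_counts_fall_back_to_one(self, caplog):
        X, Y = diagonal_system([0, 0])
        with caplog.at_level("WARNING"):
            beta = init_beta(Y, X)
        assert beta.beta0 == 1.0

    def test_beta0_is_mean_count_per_transcript(self):
        X, Y = diagonal_system([40, 60])
        beta = init_beta(Y, X)
        assert beta.beta0 == 50.0
        assert np.all(beta.beta == 50.0)

    def test_independent_of_pattern_structure(self, worked_X):
        Y = CountMatrix(worked_X.patterns, np.array([[10.0], [20.0], [70.0]]))
        assert init_beta(Y, worked_X).beta0 == 25.0  # 100 / (4 x 1)


class TestBetaUpdate:
    def test_single_transcript_gets_all_reads(self):
        X, Y = diagonal_system([100])
        beta = beta_update(Y, X, init_beta(Y, X))
        assert np.allclose(beta.beta, beta.beta0 + 100)
        assert beta.counts[0, 0] == 100.0

    def test_diagonal_allocation_exact_and_stable(self):
        X, Y = diagonal_system([30, 70])
        beta1 = beta_update(Y, X, init_beta(Y, X))
        assert np.allclose(beta1.beta[:, 0], beta1.beta0 + np.array([30, 70]))
        beta2 = beta_update(Y, X, beta1)
        assert np.array_equal(beta1.beta, beta2.beta)

    def test_zero_counts_return_prior(self, worked_X):
        Y = CountMatrix(worked_X.patterns, np.zeros((3, 2)))
        beta = init_beta(Y, worked_X)
        updated = beta_update(Y, worked_X, beta)
        assert np.all(updated.beta == updated.beta0)

    def test_literal_form_ignores_design_proportions(self):
        # one shared class, two transcripts, flat start: the default weights
        # follow x (90/10), the literal form splits evenly
        X = aq.DesignMatrix(["a", "b"], [(1, 1)], np.array([[0.9, 0.1]]))
        Y = CountMatrix(X.patterns, np.array([[100.0]]))
        start = init_beta(Y, X)
        default = beta_update(Y, X, start)
        literal = beta_update(Y, X, start, literal_eq7=True)
        assert np.allclose(default.counts[:, 0], [90.0, 10.0])
        assert np.allclose(literal.counts[:, 0], [50.0, 50.0])

    def test_read_mass_conserved(self, cluster3):
        _, X = cluster3
        rng = np.random.default_rng(0)
        Y = poisson_counts(X, rng.uniform(100, 3000, (3, 10)), seed=1)
        beta = beta_update(Y, X, init_beta(Y, X))
        assert np.allclose(beta.counts.sum(axis=0), Y.y.sum(axis=0), rtol=1e-6)


class TestXUpdate:
    def test_proportions_of_observed_reads(self):
        # transcript a dominates both classes; its updated column must be the
        # observed 60/40 split of the read counts
        X = aq.DesignMatrix(
            ["a", "b"],
            [(1, 0), (1, 1)],
            np.array([[0.5, 0.0], [0.5, 1.0]]),
        )
        Y = CountMatrix(X.patterns, np.array([[60.0], [40.0]]))
        beta = AbundanceMatrix(np.array([[100.0], [1e-6]]), 1e-7, ["a", "b"])
        updated = x_update(Y, X, beta)
        assert np.allclose(updated.x[:, 0], [0.6, 0.4], atol=1e-4)

    def test_structural_zero_persists(self, worked_X):
        rng = np.random.default_rng(1)
        Y = poisson_counts(worked_X, rng.uniform(500, 2000, (4, 20)), seed=2)
        beta = beta_update(Y, worked_X, init_beta(Y, worked_X))
        updated = x_update(Y, worked_X, beta)
        assert np.all(updated.x[~worked_X.mask] == 0)
        updated.validate()

    def test_moves_toward_generating_matrix(self, cluster3):
        # large counts, beta fixed at truth: one X step must shrink the error
        _, X_true = cluster3
        X0 = aq.apply_bias(X_true, 0.3, seed=3)
        rng = np.random.default_rng(4)
        beta_true = rng.uniform(1e4, 1e6, (3, 50))
        Y = poisson_counts(X_true, beta_true, seed=5)
        beta = AbundanceMatrix(beta_true, 1e-9 + 1, X_true.transcripts)
        updated = x_update(Y, X0, beta)
        assert np.linalg.norm(updated.x - X_true.x) < np.linalg.norm(X0.x - X_true.x)

    def test_dimension_mismatch_raises(self, worked_X):
        Y = CountMatrix(worked_X.patterns, np.ones((3, 2)))
        bad = AbundanceMatrix(np.ones((4, 3)), 1.0, worked_X.transcripts)
        with pytest.raises(ValueError):
            x_update(Y, worked_X, bad)


class TestConverged:
    def _states(self, x_prev, x_next, b_prev, b_next):
        X1 = aq.DesignMatrix(["t"], [(1,)], np.array([[1.0]]))
        X2 = aq.DesignMatrix(["t"], [(1,)], np.array([[1.0]]))
        X1.x = np.asarray(x_prev, dtype=float).reshape(1, 1)
        X2.x = np.asarray(x_next, dtype=float).reshape(1, 1)
        b1 = AbundanceMatrix(np.asarray(b_prev, dtype=float).reshape(1, 1), 1.0, ["t"])
        b2 = AbundanceMatrix(np.asarray(b_next, dtype=float).reshape(1, 1), 1.0, ["t"])
        return (X1, b1), (X2, b2)

    def test_identical_states_converged(self):
        prev, nxt = self._states(0.5, 0.5, 100, 100)
        assert converged(prev, nxt)

    def test_two_percent_change_not_converged(self):
        prev, nxt = self._states(0.5, 0.5, 100, 102)
        assert not converged(prev, nxt)

    def test_small_elements_use_absolute_floor(self):
        # 0.005 -> 0.00509: 1.8% relative, but below the 1e-4 absolute floor
        prev, nxt = self._states(0.005, 0.00509, 100, 100)
        assert converged(prev, nxt)
        prev, nxt = self._states(0.005, 0.0052, 100, 100)
        assert not converged(prev, nxt)


class TestAemFit:
    def test_diagonal_converges_in_two_iterations(self):
        X, Y = diagonal_system([30, 70, 250])
        X_hat, beta, diag = aem_fit(Y, X)
        assert diag.converged and diag.iterations <= 2
        assert np.allclose(beta.counts[:, 0], [30, 70, 250])
        assert np.array_equal(X_hat.x, X.x)

    def test_fixed_design_parameter_recovery(self, cluster3):
        _, X = cluster3
        rng = np.random.default_rng(1)
        beta_true = rng.uniform(500, 5000, (3, 50))
        Y = poisson_counts(X, beta_true, rng)
        _, beta, diag = aem_fit(Y, X, update_X=False)
        assert diag.converged
        for n in range(50):
            r = np.corrcoef(beta.counts[:, n], beta_true[:, n])[0, 1]
            assert r > 0.99

    def test_matches_brute_force_em_on_diagonal_system(self):
        # classic EM oracle: for exclusive patterns the MLE is the observed
        # count; digamma weighting cannot change an exclusive allocation
        X, Y = diagonal_system([123, 45])
        b = np.array([1.0, 1.0])
        for _ in range(200):
            b = Y.y[:, 0] * (np.eye(2) @ b) / (np.eye(2) @ b)
        _, beta, _ = aem_fit(Y, X, update_X=False)
        assert np.allclose(beta.counts[:, 0], b)

    def test_bias_correction_improves_x_and_abundances(self, cluster3):
        # counts generated from a distorted design matrix; updating X must
        # recover it and improve abundance accuracy relative to the fixed-X
        # baseline (aggregated over seeds; the distortion is random per seed)
        _, X0 = cluster3
        frob_on, frob_off, ape_on, ape_off = [], [], [], []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X_star = aq.apply_bias(X0, 0.3, rng)
            beta_true = rng.uniform(500, 5000, (3, 50))
            Y = poisson_counts(X_star, beta_true, rng)
            X_hat, beta, _ = aem_fit(Y, X0, update_X=True)
            _, beta_fixed, _ = aem_fit(Y, X0, update_X=False)
            frob_on.append(np.linalg.norm(X_hat.x - X_star.x))
            frob_off.append(np.linalg.norm(X0.x - X_star.x))
            ape_on.append(np.median(aq.median_ape(beta.counts, beta_true)))
            ape_off.append(np.median(aq.median_ape(beta_fixed.counts, beta_true)))
        assert all(on < off for on, off in zip(frob_on, frob_off))
        assert np.mean(ape_on) < np.mean(ape_off)

    def test_x_stays_near_start_when_counts_match_it(self, cluster3):
        # generating from (X0, beta) and refitting with the X step on should
        # not move X much; the prior pseudo-count induces a small drift
        _, X0 = cluster3
        rng = np.random.default_rng(7)
        Y = poisson_counts(X0, rng.uniform(500, 5000, (3, 50)), rng)
        X_hat, _, _ = aem_fit(Y, X0, update_X=True)
        assert np.max(np.abs(X_hat.x - X0.x)) < 0.1

    def test_deviance_non_increasing(self, cluster3):
        _, X0 = cluster3
        rng = np.random.default_rng(8)
        X_star = aq.apply_bias(X0, 0.3, rng)
        Y = poisson_counts(X_star, rng.uniform(500, 5000, (3, 30)), rng)
        for update_X in (False, True):
            _, _, diag = aem_fit(Y, X0, update_X=update_X)
            dev = np.array(diag.deviance)
            assert np.all(np.diff(dev) <= 1e-8 * max(1.0, dev[0]))

    def test_scale_equivariance(self, cluster3):
        _, X = cluster3
        rng = np.random.default_rng(9)
        Y = poisson_counts(X, rng.uniform(500, 5000, (3, 20)), rng)
        Y3 = CountMatrix(X.patterns, Y.y * 3)
        _, b1, _ = aem_fit(Y, X, update_X=False)
        _, b3, _ = aem_fit(Y3, X, update_X=False)
        assert np.allclose(b3.counts, 3 * b1.counts, rtol=0.01, atol=1.0)

    def test_read_mass_conserved_after_fit(self, cluster3):
        _, X = cluster3
        rng = np.random.default_rng(10)
        Y = poisson_counts(X, rng.uniform(500, 5000, (3, 20)), rng)
        _, beta, _ = aem_fit(Y, X, update_X=True)
        assert np.allclose(beta.counts.sum(axis=0), Y.y.sum(axis=0), rtol=1e-6)

    def test_non_convergence_flagged(self, cluster3, caplog):
        _, X0 = cluster3
        rng = np.random.default_rng(11)
        Y = poisson_counts(X0, rng.uniform(500, 5000, (3, 10)), rng)
        with caplog.at_level("WARNING"):
            _, _, diag = aem_fit(Y, X0, ConvergenceCriterion(max_iter=1))
        assert not diag.converged and diag.iterations == 1


class TestBuildCountMatrix:
    def test_matching_by_transcript_set(self, worked_X):
        sample = aq.EqclassCounts(
            {
                frozenset({"tx1", "tx2", "tx4"}): 7,
                frozenset({"tx1", "tx2", "tx3"}): 11,
            }
        )
        Y = build_count_matrix(worked_X, [sample])
        assert Y.y[:, 0].tolist() == [7.0, 11.0, 0.0]

    def test_unmatched_classes_dropped(self, worked_X):
        sample = aq.EqclassCounts({frozenset({"tx1"}): 5})  # no 1000 pattern
        Y = build_count_matrix(worked_X, [sample])
        assert Y.y.sum() == 0

    def test_merged_members_map_to_merged_column(self):
        X = aq.DesignMatrix(["a+b", "z"], [(1, 0), (0, 1)], np.eye(2))
        sample = aq.EqclassCounts(
            {frozenset({"a", "b"}): 4, frozenset({"a"}): 2, frozenset({"z"}): 3}
        )
        Y = build_count_matrix(X, [sample])
        assert Y.y[:, 0].tolist() == [6.0, 3.0]


def test_poisson_deviance_zero_at_exact_fit():
    X, Y = diagonal_system([10, 20])
    assert poisson_deviance(Y, X, Y.y) == 0.0
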