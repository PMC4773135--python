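import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from gbnlearn.gbn import DAG, Dataset, Intervention, OBSERVATIONAL, generate_random_dag, generate_random_gbn, sample_data
from gbnlearn.scoring import (
    Priors,
    ScoreCache,
    family_dataset,
    family_log_evidence,
    log_marginal_likelihood,
    log_predictive,
    rank_one_update,
    update_posterior,
)


def nig_evidence_oracle(design: np.ndarray, response: np.ndarray, priors: Priors) -> float:
    """Independent evidence oracle: marginalize the coefficients exactly with
    scipy's multivariate normal, then integrate the inverse-Gamma noise
    variance by quadrature on the log scale."""
    t, k = design.shape
    C = np.eye(t) + design @ design.T / priors.precision
    mean = design @ np.full(k, priors.mean)

    def f(u):  # u = log sigma^2
        s2 = math.exp(u)
        return (
            stats.invgamma.pdf(s2, priors.alpha, scale=priors.beta)
            * stats.multivariate_normal.pdf(response, mean, s2 * C)
            * s2  # Jacobian of the log substitution
        )

    val, _ = integrate.quad(f, -25, 25, limit=400)
    return math.log(val)


class TestFamilyDataset:
    def test_node_clamped_everywhere_gives_empty(self):
        dag = DAG.from_edges(2, [(0, 1)])
        ds = Dataset(
            np.array([[1.0, 0.0], [2.0, 0.0]]),
            (Intervention.knockout(1, 0.0),) * 2,
        )
        fds = family_dataset(dag, 1, ds)
        assert fds.t == 0 and fds.design.shape == (0, 2)

    def test_parentless_node_design_is_ones(self):
        dag = DAG.from_edges(2, [])
        ds = Dataset(np.arange(6.0).reshape(3, 2), (OBSERVATIONAL,) * 3)
        fds = family_dataset(dag, 0, ds)
        assert np.array_equal(fds.design, np.ones((3, 1)))
        assert np.array_equal(fds.response, [0.0, 2.0, 4.0])

    def test_enumeration_skips_clamped_instances(self):
        # instances [(1,2), (3,4)], the second clamps node 1
        dag = DAG.from_edges(2, [(0, 1)])
        ds = Dataset(
            np.array([[1.0, 2.0], [3.0, 4.0]]),
            (OBSERVATIONAL, Intervention.knockout(1, 4.0)),
        )
        fds = family_dataset(dag, 1, ds)
        assert np.array_equal(fds.design, [[1.0, 1.0]])
        assert np.array_equal(fds.response, [2.0])

    def test_clamped_parent_still_feeds_child_design(self):
        dag = DAG.from_edges(2, [(0, 1)])
        ds = Dataset(
            np.array([[0.0, 2.5]]), (Intervention.knockout(0, 0.0),)
        )
        fds = family_dataset(dag, 1, ds)
        assert np.array_equal(fds.design, [[1.0, 0.0]])


class TestUpdatePosterior:
    def test_empty_data_returns_prior(self, priors):
        prior = priors.family_prior(1)
        fds = family_dataset(
            DAG.from_edges(2, [(0, 1)]),
            1,
            Dataset(np.zeros((1, 2)), (Intervention.knockout(1, 0.0),)),
        )
        post = update_posterior(prior, fds)
        assert post.alpha == prior.alpha and post.beta == prior.beta
        assert np.allclose(post.precision, prior.precision)
        assert np.allclose(post.mean, prior.mean)

    def test_hand_worked_intercept_only_update(self, priors):
        # one observation y=2 with alpha=beta=lambda=1, mu=0
        dag = DAG.from_edges(1, [])
        ds = Dataset(np.array([[2.0]]), (OBSERVATIONAL,))
        post = update_posterior(priors.family_prior(0), family_dataset(dag, 0, ds))
        assert post.precision[0, 0] == pytest.approx(2.0)
        assert post.mean[0] == pytest.approx(1.0)
        assert post.alpha == pytest.approx(1.5)
        assert post.beta == pytest.approx(2.0)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_posterior_mean_is_ridge_solution(self, seed):
        rng = np.random.default_rng(seed)
        t, d = int(rng.integers(1, 8)), int(rng.integers(0, 3))
        X = np.column_stack([np.ones(t), rng.standard_normal((t, d))])
        y = rng.standard_normal(t)
        prior = Priors(precision=2.0).family_prior(d)
        post = update_posterior(
            prior,
            type("F", (), {"design": X, "response": y, "t": t})(),
        )
        ridge = np.linalg.solve(X.T @ X + prior.precision, prior.precision @ prior.mean + X.T @ y)
        assert np.allclose(post.mean, ridge, atol=1e-10)
        # cached inverse and determinant are consistent
        assert np.allclose(post.precision_inverse @ post.precision, np.eye(d + 1), atol=1e-8)
        assert math.exp(post.log_det_precision) == pytest.approx(
            np.linalg.det(post.precision), rel=1e-8
        )


class TestLogMarginalLikelihood:
    def test_empty_dataset_gives_zero(self, priors):
        dag = DAG.from_edges(3, [(0, 1)])
        assert log_marginal_likelihood(dag, Dataset.empty(3), priors) == 0.0

    def test_unclamped_count_in_normalization(self, priors):
        # n=2, m=2, one instance clamps one node: c = 2*2 - 1 = 3.  Doubling
        # the (2pi) normalization is visible as the -c/2 log(2pi) offset of a
        # constant-likelihood comparison; verify against the oracle instead.
        dag = DAG.from_edges(2, [])
        X = np.array([[0.4, -0.3], [0.0, 1.1]])
        ds = Dataset(X, (OBSERVATIONAL, Intervention.knockout(0, 0.0)))
        ours = log_marginal_likelihood(dag, ds, priors)
        ev0 = nig_evidence_oracle(np.ones((1, 1)), X[:1, 0], priors)
        ev1 = nig_evidence_oracle(np.ones((2, 1)), X[:, 1], priors)
        assert ours == pytest.approx(ev0 + ev1, abs=1e-6)

    def test_matches_quadrature_on_one_node_family(self, priors):
        dag = DAG.from_edges(1, [])
        y = np.array([0.3, -0.8])
        ds = Dataset(y.reshape(-1, 1), (OBSERVATIONAL,) * 2)
        ours = log_marginal_likelihood(dag, ds, priors)
        oracle = nig_evidence_oracle(np.ones((2, 1)), y, priors)
        assert math.exp(ours) == pytest.approx(math.exp(oracle), rel=1e-6)

    def test_matches_quadrature_on_two_node_family(self, priors):
        dag = DAG.from_edges(2, [(0, 1)])
        X = np.array([[0.5, 0.2], [-1.0, -0.7], [0.3, 0.9]])
        ds = Dataset(X, (OBSERVATIONAL,) * 3)
        ours = log_marginal_likelihood(dag, ds, priors)
        oracle = nig_evidence_oracle(np.ones((3, 1)), X[:, 0], priors) + nig_evidence_oracle(
            np.column_stack([np.ones(3), X[:, 0]]), X[:, 1], priors
        )
        assert math.exp(ours) == pytest.approx(math.exp(oracle), rel=1e-6)

    def test_interventions_orient_a_true_edge(self, priors, two_node_gbn):
        # knockouts of X at varying values favor X->Y over Y->X
        rng = np.random.default_rng(11)
        rows, ivs = [], []
        for val in (-2.0, -1.0, 1.0, 2.0, 3.0):
            iv = Intervention.knockout(0, val)
            rows.append(sample_data(two_node_gbn, iv, 1, rng)[0])
            ivs.append(iv)
        ds = Dataset(np.array(rows), tuple(ivs))
        fwd = log_marginal_likelihood(DAG.from_edges(2, [(0, 1)]), ds, priors)
        rev = log_marginal_likelihood(DAG.from_edges(2, [(1, 0)]), ds, priors)
        assert fwd > rev


class TestRankOneUpdate:
    def test_identity_plus_basis_vector(self, priors):
        post = update_posterior(
            priors.family_prior(1),
            type("F", (), {"design": np.zeros((0, 2)), "response": np.zeros(0), "t": 0})(),
        )
        inv, det = rank_one_update(post, np.array([1.0, 0.0]))
        assert np.allclose(inv, np.diag([0.5, 1.0]))
        assert det == pytest.approx(2.0)

    def test_zero_row_is_identity_operation(self, priors):
        post = update_posterior(
            priors.family_prior(2),
            type("F", (), {"design": np.zeros((0, 3)), "response": np.zeros(0), "t": 0})(),
        )
        inv, det = rank_one_update(post, np.zeros(3))
        assert np.allclose(inv, post.precision_inverse)
        assert det == pytest.approx(math.exp(post.log_det_precision))

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_dense_recomputation(self, seed):
        rng = np.random.default_rng(seed)
        d = int(rng.integers(1, 7))
        A = rng.standard_normal((d, d + 2))
        lam = A @ A.T + 0.5 * np.eye(d)
        post = type(
            "P",
            (),
            {
                "precision": lam,
                "precision_inverse": np.linalg.inv(lam),
                "log_det_precision": np.linalg.slogdet(lam)[1],
                "dim": d,
                "mean": np.zeros(d),
                "alpha": 1.0,
                "beta": 1.0,
            },
        )()
        v = rng.standard_normal(d)
        inv, det = rank_one_update(post, v)
        dense = lam + np.outer(v, v)
        assert np.allclose(inv, np.linalg.inv(dense), rtol=1e-10, atol=1e-12)
        assert det == pytest.approx(np.linalg.det(dense), rel=1e-10)


class TestLogPredictive:
    def test_all_clamped_gives_zero(self, priors, chain_dataset, chain_gbn):
        cache = ScoreCache(chain_dataset, priors)
        dag = chain_gbn.dag
        iv = Intervention(frozenset({(0, 0.0), (1, 0.0), (2, 0.0)}))
        assert log_predictive(dag, cache.posteriors_for(dag), np.zeros(3), iv) == 0.0

    @pytest.mark.parametrize("clamp_node", [None, 0, 2])
    def test_equals_full_recompute_difference(self, priors, chain_gbn, chain_dataset, clamp_node):
        dag = chain_gbn.dag
        cache = ScoreCache(chain_dataset, priors)
        x = sample_data(chain_gbn, count=1, seed=77)[0]
        iv = OBSERVATIONAL if clamp_node is None else Intervention.knockout(
            clamp_node, float(x[clamp_node])
        )
        lp = log_predictive(dag, cache.posteriors_for(dag), x, iv)
        full = log_marginal_likelihood(dag, chain_dataset.append(x, iv), priors) - (
            log_marginal_likelihood(dag, chain_dataset, priors)
        )
        assert lp == pytest.approx(full, abs=1e-8)

    def test_student_t_closed_form_on_empty_data(self, priors):
        # alpha=beta=lambda=1, mu=0, no data: predictive is t(df=2, loc=0, scale=sqrt 2)
        dag = DAG.from_edges(1, [])
        cache = ScoreCache(Dataset.empty(1), priors)
        lp = log_predictive(dag, cache.posteriors_for(dag), np.array([0.0]))
        assert lp == pytest.approx(stats.t.logpdf(0.0, 2, 0, math.sqrt(2)), rel=1e-10)

    def test_evidence_chain_rule(self, priors, chain_gbn):
        # log p(D1 u D2) = log p(D1) + sequential predictive increments
        dag = chain_gbn.dag
        X = sample_data(chain_gbn, count=5, seed=5)
        d1 = Dataset(X[:2], (OBSERVATIONAL,) * 2)
        total = log_marginal_likelihood(dag, d1, priors)
        ds = d1
        for k in range(2, 5):
            cache = ScoreCache(ds, priors)
            total += log_predictive(dag, cache.posteriors_for(dag), X[k])
            ds = ds.append(X[k], OBSERVATIONAL)
        assert total == pytest.approx(log_marginal_likelihood(dag, ds, priors), abs=1e-6)


class TestScoreCache:
    def test_agrees_with_direct_marginal(self, priors):
        for seed in range(5):
            dag = generate_random_dag(6, 0.4, 5, seed=seed)
            gbn = generate_random_gbn(dag, seed=seed + 100)
            rng = np.random.default_rng(seed)
            rows, ivs = [], []
            for k in range(6):
                iv = Intervention.knockout(k % 6, 0.0) if k % 2 else OBSERVATIONAL
                rows.append(sample_data(gbn, iv, 1, rng)[0])
                ivs.append(iv)
            ds = Dataset(np.array(rows), tuple(ivs))
            cache = ScoreCache(ds, priors)
            assert cache.log_marginal(dag) == pytest.approx(
                log_marginal_likelihood(dag, ds, priors), abs=1e-8
            )
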