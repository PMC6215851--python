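"""MLE, neutral simulator, deviation statistic and the exact neutrality
test at the community scale."""

import math

import numpy as np
import pytest
from scipy.stats import chisquare

from neutralassembly.etienne import (
    EtienneLikelihood,
    EtienneModel,
    I_from_m,
    deviation_statistic,
    etienne_log_likelihood,
    exact_neutrality_test,
    fit_etienne_mle,
    simulate_etienne_sample,
)
from neutralassembly.otu_io import CommunitySAD


class TestEtienneModel:
    def test_fit_dominates_probe_grid(self):
        sad = simulate_etienne_sample(20, I_from_m(0.5, 400), 400, seed=5)
        model = EtienneModel().fit(sad)
        lik = EtienneLikelihood(sad)
        for theta in (2, 10, 20, 50, 200):
            for m in (0.05, 0.3, 0.5, 0.9, 0.99):
                assert model.log_likelihood_ >= lik(theta, I_from_m(m, sad.J)) - 1e-6

    def test_theta_recovery_in_median(self):
        # known flat likelihood: only the median over replicates is stable
        estimates = []
        for s in range(20):
            sad = simulate_etienne_sample(40, I_from_m(0.9, 2000), 2000, seed=400 + s)
            estimates.append(EtienneModel().fit(sad).theta_)
        med = float(np.median(estimates))
        assert 20 <= med <= 60

    def test_boundary_community_warns(self):
        with pytest.warns(UserWarning, match="boundary"):
            model = EtienneModel().fit(CommunitySAD([7]))
        assert not model.converged_
        with pytest.warns(UserWarning, match="boundary"):
            model = EtienneModel().fit(CommunitySAD([1, 1, 1]))
        assert not model.converged_

    def test_loglik_nonpositive_and_params_consistent(self):
        sad = simulate_etienne_sample(10, 30.0, 300, seed=8)
        fit = fit_etienne_mle(sad)
        assert fit.log_likelihood < 0
        assert fit.params.J == sad.J
        assert fit.params.m == pytest.approx(
            fit.params.I / (fit.params.I + sad.J - 1), rel=1e-12
        )

    def test_sklearn_param_protocol(self):
        model = EtienneModel(tol=1e-5)
        assert model.get_params()["tol"] == 1e-5
        model.set_params(tol=1e-7)
        assert model.tol == 1e-7
        with pytest.raises(ValueError):
            model.set_params(bogus=1)


class TestSimulator:
    def test_single_individual(self):
        for seed in range(5):
            sad = simulate_etienne_sample(2.0, 3.0, 1, seed=seed)
            assert sad.abundances.tolist() == [1]

    def test_reproducible_under_seed(self):
        a = simulate_etienne_sample(15, 60.0, 800, seed=123)
        b = simulate_etienne_sample(15, 60.0, 800, seed=123)
        assert np.array_equal(a.abundances, b.abundances)

    def test_total_reads_conserved(self):
        for J in (1, 7, 250):
            assert simulate_etienne_sample(5, 10.0, J, seed=J).J == J

    def test_partition_frequencies_match_likelihood(self):
        # J = 3, theta = I = 1: exact probabilities of the three partitions
        probs = {
            part: math.exp(etienne_log_likelihood(CommunitySAD(list(part)), 1.0, 1.0))
            for part in [(3,), (2, 1), (1, 1, 1)]
        }
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)
        rng = np.random.default_rng(2024)
        counts = {part: 0 for part in probs}
        n = 20000
        for _ in range(n):
            counts[tuple(simulate_etienne_sample(1.0, 1.0, 3, rng=rng).abundances)] += 1
        res = chisquare(
            [counts[p] for p in probs], [n * probs[p] for p in probs]
        )
        assert res.pvalue > 0.01

    def test_mean_richness_increases_with_theta(self):
        rng = np.random.default_rng(7)
        mean_s = []
        for theta in (2.0, 20.0, 200.0):
            mean_s.append(
                np.mean([simulate_etienne_sample(theta, 50.0, 300, rng=rng).S for _ in range(60)])
            )
        assert mean_s[0] < mean_s[1] < mean_s[2]

    def test_invalid_parameters(self):
        for theta, I, J in [(0, 1, 5), (1, 0, 5), (1, 1, 0)]:
            with pytest.raises(ValueError):
                simulate_etienne_sample(theta, I, J)


class TestDeviationStatistic:
    def test_reference_community_examples(self):
        # two gut communities with known (logL0, logL1) pairs and rounded
        # reference q and p values
        q, p = deviation_statistic(-86.334, -85.809)
        assert q == pytest.approx(1.051, rel=2e-3)
        assert p == pytest.approx(0.3052, rel=2e-3)
        q, p = deviation_statistic(-110.238, -108.549)
        assert q == pytest.approx(3.379, rel=2e-3)
        assert p == pytest.approx(0.0660, rel=2e-3)

    def test_identical_likelihoods(self):
        q, p = deviation_statistic(-50.0, -50.0)
        assert q == 0.0 and p == 1.0

    def test_p_decreasing_in_q(self):
        qs, ps = zip(
            *(deviation_statistic(-100.0, -100.0 + d) for d in (0.1, 0.5, 1.0, 2.0, 5.0))
        )
        assert all(b > a for a, b in zip(qs, qs[1:]))
        assert all(b < a for a, b in zip(ps, ps[1:]))

    def test_one_sided_lower_tail_never_rejects(self):
        # observed more likely than neutral replicates: q < 0, p = 1
        q, p = deviation_statistic(-90.0, -95.0)
        assert q < 0 and p == 1.0
        q2, p2 = deviation_statistic(-90.0, -95.0, two_sided=True)
        assert q2 == q and p2 < 0.05

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            deviation_statistic(float("nan"), -1.0)


class TestExactTest:
    def test_deterministic_under_seed(self):
        sad = simulate_etienne_sample(12, I_from_m(0.6, 300), 300, seed=31)
        a = exact_neutrality_test(sad, n_sim=20, seed=9)
        b = exact_neutrality_test(sad, n_sim=20, seed=9)
        assert a.q == b.q and a.p == b.p
        assert np.array_equal(a.sim_log_likelihoods, b.sim_log_likelihoods)

    def test_result_contract(self):
        sad = simulate_etienne_sample(12, I_from_m(0.6, 300), 300, seed=32)
        res = exact_neutrality_test(sad, n_sim=25, seed=10)
        assert res.n_sim == 25 and res.seed == 10
        assert 0 <= res.p <= 1
        assert res.log_l0 <= 0 and res.log_l1 <= 0
        assert res.log_l1_arithmetic >= res.log_l1  # Jensen
        assert res.passes(alpha=0.05) == (res.p > 0.05)

    def test_input_validation(self):
        sad = CommunitySAD([3, 2])
        with pytest.raises(ValueError, match="n_sim"):
            exact_neutrality_test(sad, n_sim=1)
        with pytest.raises(ValueError, match="mean"):
            exact_neutrality_test(sad, n_sim=5, mean="median")
        with pytest.raises(ValueError, match="2 species"):
            exact_neutrality_test(CommunitySAD([5]), n_sim=5)
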