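"""Sloan continuous neutral model: chain dynamics, stationary beta law,
occurrence statistics, migration fit and classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from neutralassembly.otu_io import GroupMap, OTUTable
from neutralassembly.sloan import (
    SloanNeutralModel,
    SloanParams,
    species_trajectory,
    beta_density,
    compare_neutral_percentages,
    fit_sloan,
    occurrence_stats,
    predicted_occurrence,
    resampled_sloan_analysis,
    simulate_sloan_dynamics,
    stationary_distribution,
    transition_probabilities,
)


class TestTransitionProbabilities:
    def test_empty_state_can_only_gain_by_immigration(self):
        up, stay, down = transition_probabilities(0, 100, 0.2, 0.3)
        assert down == 0.0
        assert up == pytest.approx(0.2 * 0.3)

    def test_full_state_cannot_gain(self):
        up, stay, down = transition_probabilities(100, 100, 0.2, 0.3)
        assert up == 0.0

    @given(
        n=st.integers(0, 200),
        m=st.floats(0, 1),
        p=st.floats(0, 1),
    )
    @settings(derandomize=True, max_examples=200)
    def test_probabilities_sum_to_one_and_bounded(self, n, m, p):
        up, stay, down = transition_probabilities(n, 200, m, p)
        assert up + stay + down == pytest.approx(1.0, abs=1e-15)  # complement by construction
        for v in (up, stay, down):
            assert -1e-12 <= v <= 1 + 1e-12

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            transition_probabilities(-1, 10, 0.5, 0.5)
        with pytest.raises(ValueError):
            transition_probabilities(2, 10, 1.5, 0.5)


class TestDynamics:
    def test_fixed_seed_reproducible(self):
        a = simulate_sloan_dynamics(50, 0.2, 0.3, 1000, seed=4)
        b = simulate_sloan_dynamics(50, 0.2, 0.3, 1000, seed=4)
        assert np.array_equal(a, b)

    def test_pure_immigration_tracks_source(self):
        # m = 1: stationary mean of x = N/N_T equals p_i
        traj = simulate_sloan_dynamics(100, 1.0, 0.3, 200_000, seed=11, burn_in=5000)
        x = traj / 100
        mc_se = x.std() / np.sqrt(len(x) / 100)  # crude autocorrelation allowance
        assert abs(x.mean() - 0.3) < 3 * max(mc_se, 1e-3)

    def test_chain_matches_exact_stationary_distribution(self):
        # detailed-balance distribution is an independent closed-form oracle
        N_T, m, p = 60, 0.25, 0.2
        pi = stationary_distribution(N_T, m, p)
        traj = simulate_sloan_dynamics(N_T, m, p, 150_000, seed=21, burn_in=10_000)
        emp = np.bincount(traj, minlength=N_T + 1) / len(traj)
        assert np.abs(np.cumsum(emp) - np.cumsum(pi)).max() < 0.02

    def test_input_validation(self):
        with pytest.raises(ValueError):
            simulate_sloan_dynamics(50, 0.2, 0.3, 0)
        with pytest.raises(ValueError):
            simulate_sloan_dynamics(50, 0.2, 0.3, 10, n0=51)

    def test_params_container_and_species_wrapper(self):
        params = SloanParams(N_T=50, m=0.2, p=np.array([0.7, 0.3]))
        a = species_trajectory(params, 1, 500, seed=3)
        b = simulate_sloan_dynamics(50, 0.2, 0.3, 500, seed=3)
        assert np.array_equal(a, b)
        with pytest.raises(ValueError):
            SloanParams(N_T=50, m=0.2, p=np.array([0.7, 0.2]))
        with pytest.raises(ValueError):
            SloanParams(N_T=50, m=1.2, p=np.array([1.0]))
        with pytest.raises(ValueError):
            SloanParams(N_T=50, m=0.5, p=np.array([1.0]), delta=0.0)


class TestBetaLaw:
    def test_symmetric_at_half(self):
        x = np.linspace(0.05, 0.95, 19)
        d = beta_density(x, 100, 0.2, 0.5)
        assert d == pytest.approx(d[::-1])

    def test_normalization_and_mean(self):
        N_T, m, p = 100, 0.2, 0.2  # N_T m = 20
        total, _ = integrate.quad(lambda x: beta_density(x, N_T, m, p), 0, 1)
        assert total == pytest.approx(1.0, abs=1e-8)
        mean, _ = integrate.quad(lambda x: x * beta_density(x, N_T, m, p), 0, 1)
        assert mean == pytest.approx(p, abs=1e-8)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            beta_density(0.5, 100, 0.2, 0.0)  # zero shape
        with pytest.raises(ValueError):
            beta_density(1.2, 100, 0.2, 0.5)


class TestOccurrenceStats:
    @pytest.fixture
    def table(self):
        counts = np.array(
            [
                [10, 0, 90, 0],
                [20, 0, 80, 0],
                [30, 2, 68, 0],
                [15, 1, 84, 0],
                [25, 0, 75, 0],
            ]
        )
        return OTUTable(counts, [f"s{i}" for i in range(5)], ["a", "b", "c", "d"])

    def test_occurrence_fractions(self, table):
        st_ = occurrence_stats(table, ["s0", "s1"], ["s2", "s3", "s4"], detection_threshold=0.0)
        # taxon b detected in 2 of 3 destination samples; taxon d dropped
        assert st_.taxon_ids == ["a", "b", "c"]
        x = dict(zip(st_.taxon_ids, st_.x))
        assert x["a"] == 1.0 and x["c"] == 1.0
        assert x["b"] == pytest.approx(2 / 3)
        assert st_.N_T == 100
        assert st_.n_dest_samples == 3

    def test_default_threshold_is_one_read(self, table):
        st_ = occurrence_stats(table, ["s0"], ["s2", "s3", "s4"])
        assert st_.detection_threshold == pytest.approx(1 / 100)

    def test_source_mean_relative_abundance(self, table):
        st_ = occurrence_stats(table, ["s0", "s1"], ["s2"])
        p = dict(zip(st_.taxon_ids, st_.p))
        assert p["a"] == pytest.approx((0.10 + 0.20) / 2)

    def test_empty_sets_rejected(self, table):
        with pytest.raises(ValueError):
            occurrence_stats(table, [], ["s0"])


class TestSloanFit:
    def _p_grid(self, n=80, seed=0):
        rng = np.random.default_rng(seed)
        p = rng.lognormal(-7, 2, n)
        return p / p.sum()

    def test_perfect_fit_recovers_m_exactly(self):
        p = self._p_grid()
        N_T, m_true, N = 1000, 0.2, 50
        x = predicted_occurrence(p, N_T, m_true, 1 / N_T)
        fit = fit_sloan(p, x, N_T=N_T, n_dest_samples=N)
        assert fit.m_hat == pytest.approx(m_true, abs=1e-4)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_objective_at_mhat_dominates_grid(self):
        p = self._p_grid(seed=1)
        N_T, N = 500, 40
        rng = np.random.default_rng(5)
        x = np.clip(predicted_occurrence(p, N_T, 0.1, 1 / N_T) + rng.normal(0, 0.05, p.size), 0, 1)
        model = SloanNeutralModel().fit(p, x, N_T=N_T, n_dest_samples=N)

        def sse(m):
            return np.mean((x - predicted_occurrence(p, N_T, m, 1 / N_T)) ** 2)

        best = sse(model.m_)
        for m in np.linspace(0.01, 0.99, 25):
            assert best <= sse(m) + 1e-12

    def test_classification_total_exclusive_and_interval_consistent(self):
        p = self._p_grid(seed=2)
        N_T, N = 800, 30
        rng = np.random.default_rng(6)
        x = np.round(
            np.clip(predicted_occurrence(p, N_T, 0.15, 1 / N_T) + rng.normal(0, 0.1, p.size), 0, 1) * N
        ) / N
        fit = fit_sloan(p, x, N_T=N_T, n_dest_samples=N)
        assert fit.pct_neutral + fit.pct_above + fit.pct_below == pytest.approx(100.0)
        for s in fit.species:
            assert s.ci_low <= s.predicted_freq <= s.ci_high
            expected = (
                "above" if s.x_i > s.ci_high else "below" if s.x_i < s.ci_low else "neutral"
            )
            assert s.classification == expected

    def test_result_invariant_to_taxon_ordering(self):
        p = self._p_grid(seed=3)
        N_T, N = 600, 25
        rng = np.random.default_rng(7)
        x = np.clip(predicted_occurrence(p, N_T, 0.3, 1 / N_T) + rng.normal(0, 0.08, p.size), 0, 1)
        fit = fit_sloan(p, x, N_T=N_T, n_dest_samples=N)
        perm = rng.permutation(p.size)
        fit_perm = fit_sloan(p[perm], x[perm], N_T=N_T, n_dest_samples=N)
        assert fit_perm.m_hat == pytest.approx(fit.m_hat, rel=1e-6)
        assert fit_perm.pct_neutral == pytest.approx(fit.pct_neutral)

    def test_degenerate_x_gives_nan_r2_with_warning(self):
        p = np.array([0.2, 0.3, 0.5])
        x = np.ones(3)
        with pytest.warns(UserWarning, match="R\\^2"):
            fit = fit_sloan(p, x, N_T=100, n_dest_samples=10)
        assert np.isnan(fit.r_squared)

    def test_exact_binomial_interval_option(self):
        p = self._p_grid(seed=4)
        N_T, N = 500, 20
        x = predicted_occurrence(p, N_T, 0.2, 1 / N_T)
        wil = fit_sloan(p, x, N_T=N_T, n_dest_samples=N, interval="wilson")
        exact = fit_sloan(p, x, N_T=N_T, n_dest_samples=N, interval="exact")
        # Clopper-Pearson is wider than Wilson on average
        w_wid = np.mean([s.ci_high - s.ci_low for s in wil.species])
        e_wid = np.mean([s.ci_high - s.ci_low for s in exact.species])
        assert e_wid > w_wid


class TestResampledAnalysis:
    @pytest.fixture
    def dataset(self):
        from neutralassembly.synthetic import SyntheticDesign, generate_neutral_dataset

        design = SyntheticDesign(
            mode="sloan_neutral", n_groups=2, samples_per_group=15, J=400, m=0.2, seed=42
        )
        return generate_neutral_dataset(design)

    def test_same_seed_same_summary(self, dataset):
        table, groups, _ = dataset
        a = resampled_sloan_analysis(table, groups, "lean", "obese", 10, 3, seed=1)
        b = resampled_sloan_analysis(table, groups, "lean", "obese", 10, 3, seed=1)
        assert a.per_repeat.equals(b.per_repeat)

    def test_single_repeat_has_zero_sd(self, dataset):
        table, groups, _ = dataset
        s = resampled_sloan_analysis(table, groups, "lean", "lean", 10, 1, seed=2)
        assert (s.sd == 0).all()
        assert len(s.per_repeat) == 1

    def test_oversampling_small_group_warns(self, dataset):
        table, groups, _ = dataset
        with pytest.warns(UserWarning, match="replacement"):
            s = resampled_sloan_analysis(table, groups, "lean", "lean", 40, 2, seed=3)
        assert s.with_replacement

    def test_unknown_group_label(self, dataset):
        table, groups, _ = dataset
        with pytest.raises(KeyError):
            resampled_sloan_analysis(table, groups, "lean", "carnivore", 5, 2, seed=4)

    def test_exchangeable_groups_not_significantly_different(self, dataset):
        # both groups generated by the identical neutral process
        table, groups, _ = dataset
        a = resampled_sloan_analysis(table, groups, "lean", "lean", 12, 6, seed=5)
        b = resampled_sloan_analysis(table, groups, "obese", "obese", 12, 6, seed=6)
        diff = abs(a.mean["pct_neutral"] - b.mean["pct_neutral"])
        pooled = np.sqrt(a.sd["pct_neutral"] ** 2 + b.sd["pct_neutral"] ** 2)
        assert diff < 2 * pooled
        t, p = compare_neutral_percentages(a, b)
        assert p > 0.05
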