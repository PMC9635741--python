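"""Parameter sampling, PSA driver and acceptability curves."""

import numpy as np
import pytest

from dkdcea.parameters import DistributionSpec
from dkdcea.psa import (
    PSAResult,
    beta_params,
    ceac,
    draw_value,
    gamma_params,
    prob_cost_effective,
    run_psa,
    sample_parameters,
)
from dkdcea.synthetic_data import generate_parameter_set, generate_psa_specs


class TestMomentMatching:
    @pytest.mark.parametrize("mean,se", [(0.7, 0.05), (0.1, 0.02), (0.96, 0.01)])
    def test_beta_reproduces_mean_and_se(self, mean, se):
        a, b = beta_params(mean, se)
        assert a / (a + b) == pytest.approx(mean, abs=1e-12)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert np.sqrt(var) == pytest.approx(se, abs=1e-12)

    @pytest.mark.parametrize("mean,se", [(2000.0, 300.0), (5.0, 2.0)])
    def test_gamma_reproduces_mean_and_se(self, mean, se):
        shape, scale = gamma_params(mean, se)
        assert shape * scale == pytest.approx(mean, abs=1e-9)
        assert np.sqrt(shape) * scale == pytest.approx(se, abs=1e-9)

    def test_beta_se_too_large_rejected(self):
        with pytest.raises(ValueError):
            beta_params(0.5, 0.6)

    def test_beta_sample_mean_matches(self):
        spec = DistributionSpec("state:X.utility", "beta", 0.7, 0.05)
        rng = np.random.default_rng(0)
        draws = np.array([draw_value(spec, rng) for _ in range(100_000)])
        assert abs(draws.mean() - 0.7) < 3 * 0.05 / np.sqrt(100_000)
        assert np.all((draws > 0) & (draws < 1))

    def test_lognormal_median_is_point_hazard_ratio(self):
        spec = DistributionSpec("treatment:T.hr:A->B", "lognormal", 0.83, 0.15)
        rng = np.random.default_rng(1)
        draws = np.array([draw_value(spec, rng) for _ in range(50_000)])
        assert np.median(draws) == pytest.approx(0.83, rel=0.01)
        assert np.all(draws > 0)


class TestSampleParameters:
    def test_no_distributions_is_identity(self, synth_ps):
        ps = synth_ps.copy()
        ps.psa_distributions = []
        out = sample_parameters(ps, np.random.default_rng(0))
        assert out.states == ps.states and out.transitions == ps.transitions

    def test_targets_replaced_others_untouched(self, synth_ps):
        ps = synth_ps.copy()
        ps.psa_distributions = [
            DistributionSpec("state:CKD_1.utility", "beta", 0.8, 0.05)
        ]
        out = sample_parameters(ps, np.random.default_rng(3))
        assert out.state("CKD_1").utility != ps.state("CKD_1").utility
        assert out.state("Dialysis") == ps.state("Dialysis")
        assert out.transitions == ps.transitions

    def test_deterministic_given_rng_state(self, synth_ps):
        ps = synth_ps.copy()
        ps.psa_distributions = generate_psa_specs(ps, rel_se=0.1)
        a = sample_parameters(ps, np.random.default_rng(7))
        b = sample_parameters(ps, np.random.default_rng(7))
        assert a.states == b.states
        assert a.transitions == b.transitions
        assert a.treatments == b.treatments

    def test_draws_always_in_admissible_range(self, synth_ps):
        """Family choice guarantees support: probabilities/utilities in
        (0,1), costs >= 0, hazard ratios > 0, over many draws."""
        ps = synth_ps.copy()
        ps.psa_distributions = generate_psa_specs(ps, rel_se=0.3)
        rng = np.random.default_rng(11)
        for _ in range(300):
            out = sample_parameters(ps, rng)
            for s in out.states:
                assert 0.0 <= s.utility <= 1.0
                assert s.cost_healthcare >= 0 and s.cost_productivity >= 0
                assert 0.0 <= s.excess_mortality_annual < 1.0
            for t in out.transitions:
                assert 0.0 <= t.probability <= 1.0
            for tr in out.treatments:
                assert all(hr > 0 for hr in tr.hazard_ratios.values())


class TestRunPsa:
    def test_degenerate_distributions_collapse_to_deterministic(self, synth_ps):
        from dkdcea.engine import run_cohort

        ps = synth_ps.copy()
        ps.psa_distributions = [
            DistributionSpec("state:CKD_1.utility", "beta", ps.state("CKD_1").utility, 0.0)
        ]
        arms = [None, ps.treatments[0]]
        res = run_psa(ps, arms, n_iterations=2, seed=0)
        det = [run_cohort(ps, a) for a in arms]
        for j, d in enumerate(det):
            np.testing.assert_allclose(res.costs[:, j], d.total_cost, atol=1e-9)
            np.testing.assert_allclose(res.qalys[:, j], d.total_qaly, atol=1e-9)

    def test_same_seed_bit_identical(self, synth_ps):
        ps = synth_ps.copy()
        ps.psa_distributions = generate_psa_specs(ps, rel_se=0.1)
        arms = [None, ps.treatments[1]]
        a = run_psa(ps, arms, 5, seed=99)
        b = run_psa(ps, arms, 5, seed=99)
        np.testing.assert_array_equal(a.costs, b.costs)
        np.testing.assert_array_equal(a.qalys, b.qalys)

    def test_iteration_index_attached_to_failures(self, synth_ps):
        ps = synth_ps.copy()
        ps.psa_distributions = [DistributionSpec("state:Nope.utility", "beta", 0.5, 0.1)]
        with pytest.raises(RuntimeError, match="iteration 0"):
            run_psa(ps, [None], 1, seed=0)


class TestCeac:
    def _psa(self, costs, qalys, arms=("A", "B", "C")):
        costs, qalys = np.atleast_2d(costs), np.atleast_2d(qalys)
        return PSAResult(list(arms[: costs.shape[1]]), costs.astype(float),
                         qalys.astype(float), seed=0)

    def test_single_iteration_winner_takes_all(self):
        psa = self._psa([[100, 50, 200]], [[1.0, 1.1, 0.2]])
        probs = prob_cost_effective(psa, 47_000)
        assert probs == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_identical_arms_split_ties(self):
        psa = self._psa([[100, 100]], [[1.0, 1.0]], arms=("A", "B"))
        curve = ceac(psa, np.array([0.0, 1e4, 1e6]))
        np.testing.assert_allclose(curve.prob_ce, 0.5)

    def test_hand_counted_three_iterations(self):
        # at wtp=1000: NMBs per iteration decide A, B, A -> A 2/3, B 1/3
        costs = [[0, 500], [900, 100], [10, 800]]
        qalys = [[1.0, 1.2], [0.5, 0.4], [1.0, 1.0]]
        psa = self._psa(costs, qalys, arms=("A", "B"))
        curve = ceac(psa, np.array([1000.0]))
        np.testing.assert_allclose(curve.prob_ce[:, 0], [2 / 3, 1 / 3])

    def test_columns_sum_to_one(self, synth_ps):
        ps = synth_ps.copy()
        ps.psa_distributions = generate_psa_specs(ps, rel_se=0.15)
        res = run_psa(ps, [None] + list(ps.treatments), 20, seed=3)
        curve = ceac(res, np.arange(0, 150_001, 10_000, dtype=float))
        np.testing.assert_allclose(curve.prob_ce.sum(axis=0), 1.0, atol=1e-12)
        assert np.all(curve.prob_ce >= 0) and np.all(curve.prob_ce <= 1)

    def test_wtp_limits_pick_cheapest_then_most_effective(self):
        rng = np.random.default_rng(0)
        costs = rng.uniform(1e4, 1e5, size=(50, 3))
        qalys = rng.uniform(1, 10, size=(50, 3))
        psa = self._psa(costs, qalys)
        curve = ceac(psa, np.array([0.0, 1e7]))
        cheapest = np.bincount(costs.argmin(axis=1), minlength=3) / 50
        best = np.bincount(qalys.argmax(axis=1), minlength=3) / 50
        np.testing.assert_allclose(curve.prob_ce[:, 0], cheapest)
        np.testing.assert_allclose(curve.prob_ce[:, 1], best)
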