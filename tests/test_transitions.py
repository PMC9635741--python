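"""Rate/probability algebra and transition-matrix assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dkdcea.parameters import TreatmentDefinition
from dkdcea.synthetic_data import generate_parameter_set
from dkdcea.transitions import (
    annual_prob_to_cycle_prob,
    apply_hazard_ratio,
    build_transition_model,
    combine_mortality,
)

from conftest import toy_parameter_set


class TestTimescaleConversion:
    @pytest.mark.parametrize(
        "p_annual,expected",
        [
            (0.0, 0.0),
            (1.0, 1.0),
            (0.26, 1.0 - 0.74 ** (1.0 / 12.0)),  # ≈ 0.02478
        ],
    )
    def test_annual_to_monthly(self, p_annual, expected):
        assert annual_prob_to_cycle_prob(p_annual, 12) == pytest.approx(expected, abs=1e-12)

    def test_matches_rate_route(self):
        # independent route: annual rate -ln(1-p), divided across cycles
        p = 0.26
        r_monthly = -math.log(1.0 - p) / 12.0
        assert annual_prob_to_cycle_prob(p, 12) == pytest.approx(
            1.0 - math.exp(-r_monthly), abs=1e-15
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            annual_prob_to_cycle_prob(1.2, 12)


class TestHazardRatio:
    def test_identity_and_elimination(self):
        assert apply_hazard_ratio(0.05, 1.0) == pytest.approx(0.05, abs=1e-15)
        assert apply_hazard_ratio(0.05, 0.0) == 0.0

    def test_known_value(self):
        p = annual_prob_to_cycle_prob(0.26, 12)
        expected = 1.0 - math.exp(0.83 * math.log(1.0 - p))
        assert apply_hazard_ratio(p, 0.83) == pytest.approx(expected, abs=1e-12)
        assert apply_hazard_ratio(p, 0.83) == pytest.approx(0.02061, abs=5e-6)

    def test_certain_event_rejected(self):
        with pytest.raises(ValueError):
            apply_hazard_ratio(1.0, 0.5)

    @settings(derandomize=True, max_examples=200)
    @given(
        p=st.floats(0.0, 0.99),
        hr=st.floats(0.0, 3.0),
    )
    def test_commutes_with_timescale_conversion(self, p, hr):
        """HR application and annual→monthly conversion both act on the
        rate scale, so their order cannot matter."""
        a = apply_hazard_ratio(annual_prob_to_cycle_prob(p, 12), hr)
        b = annual_prob_to_cycle_prob(apply_hazard_ratio(p, hr), 12)
        assert a == pytest.approx(b, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(p=st.floats(0.01, 0.9), h1=st.floats(0.1, 2.0), h2=st.floats(0.1, 2.0))
    def test_monotone_in_hr(self, p, h1, h2):
        lo, hi = sorted([h1, h2])
        assert apply_hazard_ratio(p, lo) <= apply_hazard_ratio(p, hi)


class TestCombineMortality:
    def test_zero_excess_reduces_to_conversion(self):
        assert combine_mortality(0.0, 0.1, 12) == pytest.approx(
            annual_prob_to_cycle_prob(0.1, 12), abs=1e-15
        )

    def test_symmetry(self):
        assert combine_mortality(0.1, 0.0, 12) == combine_mortality(0.0, 0.1, 12)
        assert combine_mortality(0.07, 0.02, 12) == pytest.approx(
            combine_mortality(0.02, 0.07, 12), abs=1e-15
        )

    def test_known_value_equals_joint_survival(self):
        # two independent 10% annual risks: survival 0.9 * 0.9
        assert combine_mortality(0.1, 0.1, 12) == pytest.approx(
            1.0 - 0.81 ** (1.0 / 12.0), abs=1e-12
        )

    def test_dominates_each_component(self):
        c = combine_mortality(0.05, 0.08, 12)
        assert c >= annual_prob_to_cycle_prob(0.05, 12)
        assert c >= annual_prob_to_cycle_prob(0.08, 12)

    def test_certain_event_rejected(self):
        with pytest.raises(ValueError):
            combine_mortality(1.0, 0.1, 12)


class TestBuildTransitionModel:
    @pytest.mark.parametrize("seed", range(8))
    def test_rows_stochastic_and_no_remission_all_cycles(self, seed):
        ps = generate_parameter_set(seed=seed, n_ckd_states=(seed % 3) + 1)
        tm = build_transition_model(ps, ps.treatments[seed % 2])
        checked = set()
        for cycle in range(0, tm.n_cycles, 7):
            year = cycle // 12
            if year in checked:
                continue
            checked.add(year)
            M = tm.matrix_for_cycle(cycle)
            assert np.all(M >= 0) and np.all(M <= 1)
            np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)
            # absorbing row is the identity row
            dead = tm.expanded_names.index("Dead")
            assert M[dead, dead] == 1.0 and M[dead].sum() == 1.0
            # no mass toward strictly less-severe reported states
            rep = tm.expanded_to_reported
            for e in range(tm.n_expanded):
                for f in range(tm.n_expanded):
                    if rep[f] < rep[e]:
                        assert M[e, f] == 0.0

    def test_identity_hr_and_zero_cost_matches_untreated(self, synth_ps):
        neutral = TreatmentDefinition(
            name="neutral",
            hazard_ratios={k: 1.0 for k in synth_ps.treatments[0].hazard_ratios},
        )
        tm0 = build_transition_model(synth_ps, None)
        tm1 = build_transition_model(synth_ps, neutral)
        for cycle in (0, 60, 300):
            np.testing.assert_allclose(
                tm0.matrix_for_cycle(cycle), tm1.matrix_for_cycle(cycle), atol=1e-15
            )

    def test_three_state_toy_matches_hand_conversion(self):
        # annual probs A->B 0.26, A->Dead 0.05, B->Dead 0.4, no background
        from dkdcea.parameters import TransitionSpec

        ps = toy_parameter_set(n_alive=2, horizon_years=1.0)
        ps.transitions = [
            TransitionSpec("S0", "S1", 0.26, "annual"),
            TransitionSpec("S0", "Dead", 0.05, "annual"),
            TransitionSpec("S1", "Dead", 0.4, "annual"),
        ]
        tm = build_transition_model(ps, None)
        M = tm.matrix_for_cycle(0)
        pAB = 1.0 - 0.74 ** (1 / 12)
        pAD = 1.0 - 0.95 ** (1 / 12)
        pBD = 1.0 - 0.6 ** (1 / 12)
        expected = np.array(
            [
                [1.0 - pAB - pAD, pAB, pAD],
                [0.0, 1.0 - pBD, pBD],
                [0.0, 0.0, 1.0],
            ]
        )
        np.testing.assert_allclose(M, expected, atol=1e-12)

    def test_background_mortality_monotone_in_age(self, dkd_base):
        tm = build_transition_model(dkd_base, None)
        i = tm.expanded_names.index("CKD")
        dead = tm.expanded_names.index("Dead")
        deaths = [tm.matrix_for_cycle(12 * y)[i, dead] for y in range(0, 38)]
        assert all(b >= a for a, b in zip(deaths, deaths[1:]))

    def test_tunnel_forces_handover_after_12_cycles(self, dkd_base):
        tm = build_transition_model(dkd_base, None)
        names = tm.expanded_names
        assert "ESRD2#1" in names and "ESRD2#12" in names
        M = tm.matrix_for_cycle(0)
        k1, k12 = names.index("ESRD2#1"), names.index("ESRD2#12")
        later, dead = names.index("ESRD2.2"), names.index("Dead")
        # sub-state 1 advances (or dies); sub-state 12 hands over to ESRD2.2
        assert M[k1, k1 + 1] > 0.9 and M[k1, later] == 0.0
        assert M[k12, later] > 0.9 and M[k12, k12] == 0.0
        assert M[k12, later] + M[k12, dead] == pytest.approx(1.0, abs=1e-12)

    def test_overflowing_row_raises_with_state_and_cycle(self):
        ps = toy_parameter_set(
            n_alive=2, probs={(0, 1): 0.8, (0, 2): 0.1}, background_q=0.9
        )
        with pytest.raises(ValueError, match="S0"):
            tm = build_transition_model(ps, None)
            tm.matrix_for_cycle(0)
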