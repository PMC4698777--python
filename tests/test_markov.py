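"""Cohort engine: matrix assembly, drop-out, propagation, conservation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import igtcea as ig
from igtcea.markov import State
from igtcea.parameters import ParameterError

P1 = 1.0 - math.exp(-0.110)  # control IGT->T2DM probability, years 1-3


def params_in_ranges(draw_small=False):
    """Hypothesis strategy drawing a ParameterSet inside the declared ranges."""
    base = ig.load_parameters()
    r = base.sensitivity_ranges
    return st.builds(
        base.replace,
        dropout_year1=st.floats(*r["dropout_year1"]),
        dropout_year2=st.floats(*r["dropout_year2"]),
        incidence_igt_to_t2dm_y1_3=st.floats(*r["incidence_igt_to_t2dm_y1_3"]),
        incidence_igt_to_t2dm_y4plus=st.floats(*r["incidence_igt_to_t2dm_y4plus"]),
        rr_t2dm_year1=st.floats(*r["rr_t2dm_year1"]),
        rr_t2dm_year2=st.floats(*r["rr_t2dm_year2"]),
        p_igt_to_ngt=st.floats(*r["p_igt_to_ngt"]),
        p_ngt_to_igt=st.floats(*r["p_ngt_to_igt"]),
        rr_mortality_igt=st.floats(*r["rr_mortality_igt"]),
        rr_mortality_t2dm=st.floats(*r["rr_mortality_t2dm"]),
        discount_rate=st.floats(*r["discount_rate"]),
    )


class TestTransitionMatrix:
    @pytest.mark.parametrize("strategy", list(ig.Strategy))
    @pytest.mark.parametrize("cycle", [1, 2, 3, 4, 20])
    def test_rows_stochastic(self, strategy, cycle, base_params, life_table):
        P = ig.build_transition_matrix(cycle, 55 + cycle - 1, strategy,
                                       base_params, life_table)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((P >= 0) & (P <= 1))

    @given(params_in_ranges())
    @settings(max_examples=30)
    def test_rows_stochastic_across_ranges(self, params):
        table = ig.generate_life_table()
        for cycle, age in ((1, 55), (2, 56), (4, 90)):
            for strategy in ig.Strategy:
                P = ig.build_transition_matrix(cycle, age, strategy, params, table)
                assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_dead_row_is_identity(self, base_params, life_table):
        P = ig.build_transition_matrix(1, 55, ig.Strategy.CONTROL, base_params, life_table)
        expected = np.zeros(6)
        expected[State.DEAD] = 1.0
        assert np.array_equal(P[State.DEAD], expected)

    def test_control_igt_onset_before_mortality(self, base_params, life_table):
        """The IGT row carries the published 10.42% onset on the survivor scale."""
        P = ig.build_transition_matrix(1, 55, ig.Strategy.CONTROL, base_params, life_table)
        surv = 1.0 - P[State.IGT_DROP, State.DEAD]
        assert P[State.IGT_DROP, State.T2DM] / surv == pytest.approx(P1, abs=1e-12)
        assert round(100 * P1, 2) == 10.42

    def test_sms_year2_retained_row_hand_assembled(self, base_params, life_table):
        """T2DM entry = 0.0625 x (1 - q_IGT) under mortality-first composition."""
        age = 56
        q_bg = life_table.death_probability(age)
        q_igt = 1.0 - (1.0 - q_bg) ** base_params.rr_mortality_igt
        P = ig.build_transition_matrix(2, age, ig.Strategy.SMS, base_params, life_table)
        assert P[State.IGT_RET, State.T2DM] == pytest.approx(
            0.60 * P1 * (1.0 - q_igt), abs=1e-9
        )
        # retention label preserved on regression to NGT
        assert P[State.IGT_RET, State.NGT_RET] > 0
        assert P[State.IGT_RET, State.NGT_DROP] == 0

    def test_t2dm_absorbing_except_death(self, base_params, life_table):
        P = ig.build_transition_matrix(5, 60, ig.Strategy.CONTROL, base_params, life_table)
        row = P[State.T2DM]
        assert row[State.T2DM] + row[State.DEAD] == pytest.approx(1.0, abs=1e-12)
        assert row[[State.NGT_RET, State.IGT_RET, State.NGT_DROP, State.IGT_DROP]].sum() == 0

    def test_year4_uses_late_incidence(self, base_params, life_table):
        P3 = ig.build_transition_matrix(3, 57, ig.Strategy.CONTROL, base_params, life_table)
        P4 = ig.build_transition_matrix(4, 58, ig.Strategy.CONTROL, base_params, life_table)
        assert P4[State.IGT_DROP, State.T2DM] < P3[State.IGT_DROP, State.T2DM]


class TestDropout:
    def test_year1_split(self, base_params):
        occ = np.zeros(6)
        occ[State.IGT_RET] = 1.0
        out = ig.apply_dropout(occ, 1, base_params)
        assert out[State.IGT_RET] == pytest.approx(0.6111)
        assert out[State.IGT_DROP] == pytest.approx(0.3889)
        assert out.sum() == pytest.approx(1.0, abs=1e-15)

    def test_zero_dropout_is_identity(self, base_params):
        p = base_params.replace(dropout_year1=0.0)
        occ = np.zeros(6)
        occ[State.IGT_RET] = 0.7
        occ[State.NGT_RET] = 0.3
        assert np.array_equal(ig.apply_dropout(occ, 1, p), occ)

    def test_full_dropout_empties_retained_strata(self, base_params, life_table):
        p = base_params.replace(dropout_year1=1.0)
        sms = ig.run_cohort(ig.Strategy.SMS, p, life_table, horizon=10)
        ctrl = ig.run_cohort(ig.Strategy.CONTROL, p, life_table, horizon=10)
        assert np.all(sms.occupancy[:, [State.NGT_RET, State.IGT_RET]][1:] == 0)
        # initial rows differ only by the retention label; from cycle 1 on
        # the trajectories are identical
        assert np.allclose(sms.occupancy[1:], ctrl.occupancy[1:], atol=1e-15)

    def test_invalid_cycle(self, base_params):
        with pytest.raises(ParameterError):
            ig.apply_dropout(np.zeros(6), 3, base_params)


class TestRunCohort:
    def test_single_cycle_control_immortal(self, base_params, immortal_table):
        trace = ig.run_cohort(ig.Strategy.CONTROL, base_params, immortal_table,
                              horizon=1, start_age=55)
        occ = trace.occupancy[1]
        assert occ[State.NGT_DROP] == pytest.approx(0.1620, abs=1e-12)
        assert occ[State.IGT_DROP] == pytest.approx(1.0 - 0.1620 - P1, abs=1e-12)
        assert occ[State.T2DM] == pytest.approx(P1, abs=1e-12)

    def test_two_cycle_cumulative_onset_immortal(self, base_params, immortal_table):
        trace = ig.run_cohort(ig.Strategy.CONTROL, base_params, immortal_table,
                              horizon=2, start_age=55)
        expected = P1 + (1.0 - 0.1620 - P1) * P1  # = 0.18061 by hand
        assert trace.cumulative_onset == pytest.approx(expected, abs=1e-12)
        assert round(expected, 5) == 0.18061

    def test_rr_one_makes_arms_identical(self, base_params, life_table):
        p = base_params.replace(rr_t2dm_year1=1.0, rr_t2dm_year2=1.0)
        sms = ig.run_cohort(ig.Strategy.SMS, p, life_table, horizon=50)
        ctrl = ig.run_cohort(ig.Strategy.CONTROL, p, life_table, horizon=50)
        # collapse the retention split: clinical occupancy must agree exactly
        for trace_pair in zip(sms.occupancy, ctrl.occupancy):
            s, c = trace_pair
            assert s[State.NGT_RET] + s[State.NGT_DROP] == pytest.approx(
                c[State.NGT_RET] + c[State.NGT_DROP], abs=1e-12
            )
            assert s[State.IGT_RET] + s[State.IGT_DROP] == pytest.approx(
                c[State.IGT_RET] + c[State.IGT_DROP], abs=1e-12
            )
            assert s[State.T2DM] == pytest.approx(c[State.T2DM], abs=1e-12)
            assert s[State.DEAD] == pytest.approx(c[State.DEAD], abs=1e-12)

    @given(params_in_ranges())
    @settings(max_examples=20)
    def test_mass_conserved_everywhere(self, params):
        table = ig.generate_life_table()
        for strategy in ig.Strategy:
            trace = ig.run_cohort(strategy, params, table, horizon=50)
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
            dead = trace.occupancy[:, State.DEAD]
            assert np.all(np.diff(dead) >= -1e-15)
            assert np.all(np.diff(np.cumsum(trace.onsets)) >= -1e-15)
            assert trace.cumulative_onset <= 1.0 + 1e-12

    def test_onset_monotone_in_incidence(self, base_params, life_table):
        lo, hi = base_params.sensitivity_ranges["incidence_igt_to_t2dm_y1_3"]
        onsets = []
        for rate in np.linspace(lo, hi, 5):
            p = base_params.replace(incidence_igt_to_t2dm_y1_3=float(rate))
            onsets.append(
                ig.run_cohort(ig.Strategy.CONTROL, p, life_table, horizon=20).cumulative_onset
            )
        assert np.all(np.diff(onsets) > 0)

    def test_horizon_beyond_table_errors(self, base_params):
        short = ig.generate_life_table(age_range=range(55, 60))
        with pytest.raises(ParameterError, match="extend"):
            ig.run_cohort(ig.Strategy.CONTROL, base_params, short, horizon=50)

    def test_trace_export_shapes(self, base_params, life_table):
        trace = ig.run_cohort(ig.Strategy.SMS, base_params, life_table, horizon=5)
        tidy = trace.to_frame()
        assert len(tidy) == 6 * 6  # (horizon + 1) cycles x 6 states
        assert set(tidy.columns) == {"cycle", "state", "occupancy"}
        summary = trace.summary_frame()
        assert len(summary) == 5
        assert summary["new_onsets"].sum() == pytest.approx(trace.cumulative_onset)
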