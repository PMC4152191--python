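"""Transition-matrix construction, probability conversion, cohort propagation."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from depmark import (
    DepmarkError,
    InfeasibleParametersError,
    build_transition_matrix,
    convert_probability,
    run_cohort,
    trace_oracle,
)
from depmark.engine import TransitionMatrix

from conftest import make_toy_config


class TestConvertProbability:
    @pytest.mark.parametrize(
        "p,t_from,t_to,expected",
        [
            (0.105, 1.0, 0.25, 1.0 - 0.895**0.25),  # annual turnover -> 3-month
            (0.0, 1.0, 0.25, 0.0),
            (1.0, 1.0, 0.25, 1.0),
            (0.3, 0.25, 0.25, 0.3),  # identity when periods coincide
        ],
    )
    def test_closed_form(self, p, t_from, t_to, expected):
        assert convert_probability(p, t_from, t_to) == pytest.approx(
            expected, abs=1e-12
        )

    def test_annual_turnover_printed_value(self):
        # 10.5%/year re-expressed on the 3-month cycle
        assert convert_probability(0.105, 1.0, 0.25) == pytest.approx(
            0.02736, abs=1e-5
        )

    @given(p=st.floats(min_value=0.0, max_value=1.0 - 1e-12))
    @settings(max_examples=200, deadline=None)
    def test_round_trip(self, p):
        down = convert_probability(p, 1.0, 0.25)
        assert convert_probability(down, 0.25, 1.0) == pytest.approx(p, abs=1e-12)

    @given(
        p1=st.floats(min_value=0.0, max_value=1.0),
        p2=st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_p(self, p1, p2):
        lo, hi = sorted((p1, p2))
        assert convert_probability(lo, 1.0, 0.25) <= convert_probability(hi, 1.0, 0.25)

    def test_domain_errors(self):
        with pytest.raises(DepmarkError):
            convert_probability(1.2, 1.0, 0.25)
        with pytest.raises(DepmarkError):
            convert_probability(0.5, 0.0, 0.25)


class TestBuildTransitionMatrix:
    def test_all_hazards_zero_gives_identity(self, fixture_configs):
        cfg = fixture_configs["absenteeism_blue"].model_copy(deep=True)
        t = cfg.transitions
        for f in (
            "remission_treated_12m",
            "remission_untreated_12m",
            "relapse_treated_12m",
            "relapse_untreated_12m",
            "treatment_initiation_12m",
            "early_retirement_annual",
        ):
            setattr(t, f, 0.0)
        for band in t.baseline_mortality_annual:
            band.male = band.female = 0.0
        M = build_transition_matrix(t, cfg.states, 0, cfg)
        np.testing.assert_allclose(M.entries, np.eye(len(cfg.states)), atol=1e-15)

    def test_no_retirement_from_age_50(self, fixture_configs):
        """The early-retirement pathway closes once the cohort reaches 50."""
        cfg = fixture_configs["absenteeism_blue"].model_copy(deep=True)
        cfg.transitions.cohort_start_age = 50.0
        M = build_transition_matrix(cfg.transitions, cfg.states, 0, cfg)
        i_ret = M.index("retired")
        col = M.entries[:, i_ret].copy()
        col[i_ret] = 0.0
        assert np.all(col == 0.0)

    def test_under_50_retirement_column_positive(self, fixture_configs):
        cfg = fixture_configs["absenteeism_blue"]
        M = build_transition_matrix(cfg.transitions, cfg.states, 0, cfg)
        i_ret = M.index("retired")
        employed = [i for i, s in enumerate(cfg.states) if s.employed]
        assert all(M.entries[i, i_ret] > 0 for i in employed)

    def test_suicide_multiplier_on_depressed_rows(self, fixture_configs):
        """Depressed rows get the excess-mortality product, recovered the base."""
        cfg = fixture_configs["absenteeism_blue"].model_copy(deep=True)
        t = cfg.transitions
        # pick annual mortality so the per-cycle probability is exactly 0.01
        annual = 1.0 - (1.0 - 0.01) ** 4
        for band in t.baseline_mortality_annual:
            band.male = band.female = annual
        t.suicide_mortality_multiplier = 1.5
        M = build_transition_matrix(t, cfg.states, 0, cfg)
        i_dead = M.index("deceased")
        for i, s in enumerate(cfg.states):
            if not s.alive or s.absorbing:
                continue
            expected = 0.015 if s.depressed else 0.01
            assert M.entries[i, i_dead] == pytest.approx(expected, abs=1e-12)

    def test_infeasible_named_transitions_identify_state(self, fixture_configs):
        cfg = fixture_configs["absenteeism_blue"].model_copy(deep=True)
        cfg.transitions.remission_untreated_12m = 1.0
        cfg.transitions.treatment_initiation_12m = 1.0
        with pytest.raises(InfeasibleParametersError) as exc:
            build_transition_matrix(cfg.transitions, cfg.states, 0, cfg)
        assert exc.value.state == "depressed_untreated"

    @settings(max_examples=1000, deadline=None)
    @given(data=st.data())
    def test_row_stochastic_over_random_parameters(self, data, fixture_configs):
        """Every built matrix is row-stochastic to 1e-12 with entries in [0,1]."""
        cfg = fixture_configs["absenteeism_blue"].model_copy(deep=True)
        t = cfg.transitions
        prob = st.floats(min_value=0.0, max_value=0.95)
        for f in (
            "remission_treated_12m",
            "remission_untreated_12m",
            "relapse_treated_12m",
            "relapse_untreated_12m",
            "treatment_initiation_12m",
            "early_retirement_annual",
        ):
            setattr(t, f, data.draw(prob, label=f))
        t.suicide_mortality_multiplier = data.draw(
            st.floats(min_value=1.0, max_value=5.0), label="mult"
        )
        for band in t.baseline_mortality_annual:
            band.male = data.draw(st.floats(min_value=0.0, max_value=0.2))
            band.female = data.draw(st.floats(min_value=0.0, max_value=0.2))
        try:
            M = build_transition_matrix(t, cfg.states, 0, cfg).entries
        except InfeasibleParametersError:
            # correctly rejected: named per-cycle transitions exceeded 1
            assume(False)
        assert np.all(M >= 0.0) and np.all(M <= 1.0)
        np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)


class TestRunCohort:
    def test_toy_chain_survival(self):
        """Per-cycle death 0.1 leaves 1000 x 0.9^4 = 656.1 alive at cycle 4."""
        trace = run_cohort(make_toy_config(death_per_cycle=0.1, horizon=4))
        i_alive = trace.state_names.index("alive")
        assert trace.occupancy[4, i_alive] == pytest.approx(656.1, abs=1e-6)

    def test_conservation(self, fixture_configs):
        for cfg in fixture_configs.values():
            trace = run_cohort(cfg)
            np.testing.assert_allclose(
                trace.occupancy.sum(axis=1), cfg.cohort_size, atol=1e-9
            )

    def test_identity_matrix_constant_occupancy(self, fixture_configs):
        cfg = fixture_configs["absenteeism_blue"].model_copy(deep=True)
        t = cfg.transitions
        for f in (
            "remission_treated_12m",
            "remission_untreated_12m",
            "relapse_treated_12m",
            "relapse_untreated_12m",
            "treatment_initiation_12m",
            "early_retirement_annual",
        ):
            setattr(t, f, 0.0)
        for band in t.baseline_mortality_annual:
            band.male = band.female = 0.0
        trace = run_cohort(cfg)
        for t_idx in range(1, cfg.horizon + 1):
            np.testing.assert_allclose(trace.occupancy[t_idx], trace.occupancy[0])

    def test_absorbing_monotonicity(self, fixture_configs):
        for cfg in fixture_configs.values():
            cfg = cfg.model_copy(deep=True)
            cfg.run.horizon = 20
            trace = run_cohort(cfg)
            for name in ("deceased", "retired"):
                col = trace.occupancy[:, trace.state_names.index(name)]
                assert np.all(np.diff(col) >= -1e-9)

    def test_trace_length_and_ages(self, fixture_configs):
        cfg = fixture_configs["absenteeism_blue"]
        trace = run_cohort(cfg)
        assert trace.occupancy.shape[0] == cfg.horizon + 1
        assert trace.ages[0] == cfg.transitions.cohort_start_age
        assert trace.ages[-1] == pytest.approx(
            cfg.transitions.cohort_start_age + cfg.horizon * cfg.cycle_length
        )

    def test_trace_dataframe_export(self, fixture_configs):
        df = run_cohort(fixture_configs["absenteeism_blue"]).to_dataframe()
        assert list(df.columns[:2]) == ["cycle", "age"]
        assert len(df) == fixture_configs["absenteeism_blue"].horizon + 1


class TestTraceOracle:
    def test_t0_returns_v0(self):
        M = np.array([[0.9, 0.1], [0.0, 1.0]])
        v0 = np.array([1000.0, 0.0])
        np.testing.assert_allclose(trace_oracle(M, v0, 0), v0)

    def test_t1_single_step(self):
        M = np.array([[0.9, 0.1], [0.0, 1.0]])
        v0 = np.array([1000.0, 0.0])
        np.testing.assert_allclose(trace_oracle(M, v0, 1), v0 @ M)

    def test_matches_run_cohort_on_toy_chain(self):
        cfg = make_toy_config(death_per_cycle=0.1, horizon=4)
        trace = run_cohort(cfg)
        from depmark import build_transition_matrix

        M = build_transition_matrix(cfg.transitions, cfg.states, 0, cfg)
        v0 = trace.occupancy[0]
        for t in range(5):
            np.testing.assert_allclose(
                trace_oracle(M, v0, t), trace.occupancy[t], atol=1e-10
            )

    def test_rejects_non_square(self):
        with pytest.raises(DepmarkError):
            trace_oracle(np.ones((2, 3)), np.ones(2), 1)

    def test_transition_matrix_wrapper_accepted(self):
        M = TransitionMatrix(
            entries=np.array([[0.5, 0.5], [0.0, 1.0]]), state_names=["a", "b"]
        )
        out = trace_oracle(M, np.array([1.0, 0.0]), 2)
        np.testing.assert_allclose(out, [0.25, 0.75])
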