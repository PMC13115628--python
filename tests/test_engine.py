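"""Markov engine: matrix assembly, discounting, cohort simulation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cardioroi import (
    CONTROL,
    DEATH,
    INTERVENTION,
    PSASettings,
    ScenarioConfig,
    StateTable,
    TransitionRow,
    TransitionTable,
    ValidationError,
    build_matrix,
    discount_factor,
    run_cohort,
)
from conftest import FIXED, flat_life_table, random_model, two_state_model


class TestDiscountFactor:
    def test_zero_time_identity(self):
        assert discount_factor(0.03, 0) == 1.0

    def test_one_year_at_3pct(self):
        assert discount_factor(0.03, 1) == pytest.approx(1 / 1.03, abs=1e-12)

    @pytest.mark.parametrize("k", [0, 1, 7, 50])
    def test_zero_rate_identity(self, k):
        assert discount_factor(0.0, k) == 1.0

    def test_negative_cycle_rejected(self):
        with pytest.raises(ValidationError):
            discount_factor(0.03, -1)


class TestBuildMatrix:
    def test_healthy_row_stay_probability(self, states, transitions):
        # exits: 3 specific incidence edges + 4 acute-event wildcard edges + death
        lt = flat_life_table(0.002)
        m = build_matrix(states, transitions, lt, 40)
        i = m.state_ids.index("healthy")
        assert m.probs[i, i] == pytest.approx(0.9401, abs=1e-12)

    def test_rrr_halves_named_edge_and_raises_stay(self, states, transitions):
        lt = flat_life_table(0.002)
        base = build_matrix(states, transitions, lt, 40)
        adj = build_matrix(states, transitions, lt, 40, {"pre_dm->dm": 0.5})
        i = base.state_ids.index("pre_dm")
        j = base.state_ids.index("dm")
        assert base.probs[i, j] == pytest.approx(0.0112)
        assert adj.probs[i, j] == pytest.approx(0.0056)
        assert adj.probs[i, i] - base.probs[i, i] == pytest.approx(0.0056)

    def test_wildcard_adjustment_applies_to_every_expansion(self, states,
                                                            transitions):
        lt = flat_life_table(0.0)
        adj = build_matrix(states, transitions, lt, 40, {"ANY->mi": 0.5})
        j = adj.state_ids.index("mi")
        for sid in ("healthy", "dm", "stroke"):
            i = adj.state_ids.index(sid)
            assert adj.probs[i, j] == pytest.approx(0.0005)

    def test_empty_transition_table_gives_identity_plus_mortality(self, states):
        tt = TransitionTable(
            [TransitionRow("ANY", DEATH, None, FIXED, "age_specific")], states
        )
        lt = flat_life_table(0.01)
        m = build_matrix(states, tt, lt, 40)
        n = len(states)
        assert np.allclose(np.diag(m.probs)[:n], 0.99)
        assert np.allclose(m.probs[:n, n], 0.01)

    def test_death_row_absorbing_and_rows_sum_to_one(self, states, transitions,
                                                     life_table):
        m = build_matrix(states, transitions, life_table, 63)
        assert m.probs[-1, -1] == 1.0
        assert np.allclose(m.probs.sum(axis=1), 1.0, atol=1e-12)

    def test_exits_exceeding_one_rejected_with_state_and_age(self, states):
        tt = TransitionTable(
            [
                TransitionRow("healthy", "dm", 0.7, FIXED),
                TransitionRow("healthy", "obesity", 0.35, FIXED),
                TransitionRow("ANY", DEATH, None, FIXED, "age_specific"),
            ],
            states,
        )
        with pytest.raises(ValidationError, match="healthy.*age 40"):
            build_matrix(states, tt, flat_life_table(0.0), 40)

    def test_unknown_adjustment_edge_rejected(self, states, transitions,
                                              life_table):
        with pytest.raises(ValidationError, match="unknown edge"):
            build_matrix(states, transitions, life_table, 40, {"dm->healthy": 0.5})

    def test_remission_extra_edge_enters_matrix(self, states, transitions,
                                                life_table):
        m = build_matrix(
            states, transitions, life_table, 40, extra_edges={"obesity->healthy": 0.2}
        )
        i = m.state_ids.index("obesity")
        j = m.state_ids.index("healthy")
        assert m.probs[i, j] == pytest.approx(0.2)


def immortal_healthy_config(horizon=5, rate=0.0, program=0.0):
    return ScenarioConfig(
        horizon=horizon,
        discount_rate=rate,
        baseline_distribution={"healthy": 1.0},
        program_cost_per_member_year=program,
        psa=PSASettings(n_iter=1),
    )


class TestRunCohort:
    def test_immortal_healthy_cohort_undiscounted(self):
        st, tt = two_state_model()
        trace = run_cohort(immortal_healthy_config(), st, tt, flat_life_table(0.0))
        assert trace.total_qaly == pytest.approx(5.0)
        assert trace.total_cost == 0.0

    def test_immortal_healthy_cohort_discounted_closed_form(self):
        st, tt = two_state_model()
        cfg = immortal_healthy_config(rate=0.03)
        trace = run_cohort(cfg, st, tt, flat_life_table(0.0))
        expected = sum(1 / 1.03**t for t in range(5))  # 4.717098...
        assert trace.total_qaly == pytest.approx(expected, abs=1e-12)
        assert trace.total_qaly_undiscounted == pytest.approx(5.0)

    def test_single_sick_state_one_year_accrual(self):
        # a member parked in a $1200 / utility-0.88 state accrues exactly that
        st, tt = two_state_model(cost=1200.0, utility=0.88)
        cfg = ScenarioConfig(
            horizon=1,
            discount_rate=0.0,
            baseline_distribution={"sick": 1.0},
            psa=PSASettings(n_iter=1),
        )
        trace = run_cohort(cfg, st, tt, flat_life_table(0.0))
        assert trace.total_cost == pytest.approx(1200.0)
        assert trace.total_qaly == pytest.approx(0.88)

    def test_program_cost_accrues_per_alive_member_year(self):
        st, tt = two_state_model()
        cfg = immortal_healthy_config(rate=0.03, program=720.0)
        trace = run_cohort(cfg, st, tt, flat_life_table(0.0), INTERVENTION)
        expected = 720.0 * sum(1 / 1.03**t for t in range(5))
        assert trace.total_program_cost == pytest.approx(expected)
        control = run_cohort(cfg, st, tt, flat_life_table(0.0), CONTROL)
        assert control.total_program_cost == 0.0

    def test_dead_members_stop_accruing_program_cost(self):
        st, tt = two_state_model()
        cfg = immortal_healthy_config(program=720.0)
        trace = run_cohort(cfg, st, tt, flat_life_table(0.5), INTERVENTION)
        # alive fraction at cycles 0..4: 1, .5, .25, .125, .0625
        assert trace.total_program_cost == pytest.approx(720.0 * 1.9375)

    def test_unparameterized_baseline_state_rejected(self, states, transitions,
                                                     life_table):
        cfg = ScenarioConfig(baseline_distribution={"gout": 1.0})
        with pytest.raises(ValidationError, match="gout"):
            run_cohort(cfg, states, transitions, life_table)

    def test_half_cycle_correction_averages_occupancy(self):
        st, tt = two_state_model()
        cfg = immortal_healthy_config(horizon=1).with_overrides(
            half_cycle_correction=True
        )
        trace = run_cohort(cfg, st, tt, flat_life_table(0.5))
        assert trace.total_qaly == pytest.approx(0.75)  # (1 + 0.5) / 2


class TestProperties:
    @given(st.integers(0, 10_000))
    def test_occupancy_conservation(self, seed):
        rng = np.random.default_rng(seed)
        stt, tt, lt, cfg = random_model(rng)
        for arm in (CONTROL, INTERVENTION):
            trace = run_cohort(cfg, stt, tt, lt, arm)
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(trace.occupancy >= -1e-15)

    @given(st.integers(0, 10_000))
    def test_matrix_power_oracle_under_constant_mortality(self, seed):
        rng = np.random.default_rng(seed)
        stt, tt, lt, cfg = random_model(rng)
        trace = run_cohort(cfg, stt, tt, lt)
        M = build_matrix(stt, tt, lt, cfg.start_age).probs
        v0 = trace.occupancy[0]
        for t in range(cfg.horizon + 1):
            expected = v0 @ np.linalg.matrix_power(M, t)
            assert np.allclose(trace.occupancy[t], expected, atol=1e-10)

    @given(st.integers(0, 10_000), st.floats(1.1, 5.0))
    def test_raising_a_cost_never_decreases_total_cost(self, seed, factor):
        rng = np.random.default_rng(seed)
        stt, tt, lt, cfg = random_model(rng)
        sick = stt.state_ids[-1]
        bumped = stt.with_updates(annual_cost={sick: stt[sick].annual_cost * factor})
        for arm in (CONTROL, INTERVENTION):
            base = run_cohort(cfg, stt, tt, lt, arm)
            more = run_cohort(cfg, bumped, tt, lt, arm)
            assert more.total_cost >= base.total_cost - 1e-9

    @given(st.integers(0, 10_000))
    def test_raising_discount_rate_never_increases_qalys(self, seed):
        rng = np.random.default_rng(seed)
        stt, tt, lt, cfg = random_model(rng)
        hi = cfg.with_overrides(discount_rate=cfg.discount_rate + 0.05)
        assert (
            run_cohort(hi, stt, tt, lt).total_qaly
            <= run_cohort(cfg, stt, tt, lt).total_qaly + 1e-12
        )

    def test_intervention_with_rrr_dominates_on_qalys(self, states, transitions,
                                                      life_table, default_config):
        # progression risk reduced, zero program cost: QALYs can only improve
        cfg = default_config.with_overrides(program_cost_per_member_year=0.0)
        treated = run_cohort(cfg, states, transitions, life_table, INTERVENTION)
        control = run_cohort(cfg, states, transitions, life_table, CONTROL)
        assert treated.total_qaly >= control.total_qaly
        assert treated.total_cost <= control.total_cost
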