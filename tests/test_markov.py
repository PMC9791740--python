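"""Markov cohort engine: matrix construction, propagation, discounting."""

import numpy as np
import pytest

from tkicea.markov import (
    IDX,
    N_STATES,
    STATES,
    TransitionError,
    TransitionMatrix,
    build_rewards,
    build_transition_matrix,
    discount_factor,
    run_arm,
    run_cohort,
)
from tkicea.tree import PhaseOutcome, StructureToggles


class TestMatrix:
    def test_cr_stay_probabilities(self, params):
        im = build_transition_matrix("imatinib", params).matrix
        da = build_transition_matrix("dasatinib", params).matrix
        assert im[IDX["CR"], IDX["CR"]] == pytest.approx(1 - 0.1000 - 0.0879)
        assert da[IDX["CR"], IDX["CR"]] == pytest.approx(1 - 0.0537 - 0.0304)

    def test_death_row_is_identity(self, params):
        for arm in ("imatinib", "dasatinib"):
            m = build_transition_matrix(arm, params).matrix
            expected = np.zeros(N_STATES)
            expected[IDX["DEATH"]] = 1.0
            assert np.array_equal(m[IDX["DEATH"]], expected)

    def test_rows_sum_to_one(self, params):
        for arm in ("imatinib", "dasatinib"):
            m = build_transition_matrix(arm, params).matrix
            assert np.abs(m.sum(axis=1) - 1.0).max() < 1e-12

    def test_noncr_competing_risks(self, params):
        m = build_transition_matrix("imatinib", params).matrix
        for s in ("NONCR", "RELAPSE"):
            assert m[IDX[s], IDX["HSCT_CR1"]] == pytest.approx(0.1 * 0.4)
            assert m[IDX[s], IDX["HSCT_FAIL"]] == pytest.approx(0.1 * 0.6)
            assert m[IDX[s], IDX["DEATH"]] == pytest.approx(0.6)
            assert m[IDX[s], IDX[s]] == pytest.approx(0.3)

    def test_tunnel_chain_advances_yearly(self, params):
        m = build_transition_matrix("dasatinib", params).matrix
        stay = 1 - 0.0582 - 0.23
        for a, b in [("HSCT_CR1", "HSCT_CR2"), ("HSCT_CR4", "HSCT_CR5"),
                     ("HSCT_CR5", "HSCT_CR_LATE")]:
            assert m[IDX[a], IDX[b]] == pytest.approx(stay)
        assert m[IDX["HSCT_CR_LATE"], IDX["HSCT_CR_LATE"]] == pytest.approx(stay)

    def test_pathological_inputs_rejected(self, params):
        bad = params.with_values({"im_death_cr_maint": 0.95})
        with pytest.raises(TransitionError):
            build_transition_matrix("imatinib", bad)


class TestDiscounting:
    @pytest.mark.parametrize(
        "t, r, expected",
        [(0, 0.05, 1.0), (1, 0.05, 1 / 1.05), (10, 0.05, 1.05 ** -10)],
    )
    def test_discount_factor(self, t, r, expected):
        assert discount_factor(t, r) == pytest.approx(expected, rel=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(1, -0.01)

    def test_totals_decrease_with_discount_rate(self, params, toggles):
        lo = params.with_values({"discount_rate": 0.03})
        hi = params.with_values({"discount_rate": 0.08})
        for arm in ("imatinib", "dasatinib"):
            r_lo = run_arm(arm, lo, toggles)
            r_hi = run_arm(arm, hi, toggles)
            assert r_hi.total_cost <= r_lo.total_cost
            assert r_hi.total_qalys <= r_lo.total_qalys


def _toy_death_matrix(p_death: float) -> TransitionMatrix:
    """11-state matrix where CR dies with p_death and everything else idles."""
    m = np.eye(N_STATES)
    m[IDX["CR"], IDX["CR"]] = 1 - p_death
    m[IDX["CR"], IDX["DEATH"]] = p_death
    return TransitionMatrix(arm="imatinib", matrix=m, p_transplant=0.0,
                            transplant_cost=0.0)


def _phase(cr=1.0, noncr=0.0, death=0.0, cost=0.0, qalys=0.0, elapsed=0.0):
    return PhaseOutcome(
        state_distribution={"CR": cr, "nonCR": noncr, "death": death},
        cost=cost, qalys=qalys, elapsed=elapsed,
    )


class TestCohortPropagation:
    def test_toy_two_state_chain_qalys(self):
        """Alive (u=1) with 50% annual mortality, 2 undiscounted cycles:
        expected QALYs 0.5 + 0.25 = 0.75 under end-cycle accrual."""
        utils = np.zeros(N_STATES)
        utils[IDX["CR"]] = 1.0
        res = run_cohort(_phase(), _toy_death_matrix(0.5),
                         (np.zeros(N_STATES), utils), horizon=2, discount_rate=0.0)
        assert res.total_qalys == pytest.approx(0.75)
        assert res.total_cost == 0.0

    def test_all_death_initial_keeps_tree_values_only(self, params, toggles):
        from tkicea.markov import build_rewards, build_transition_matrix

        phase = _phase(cr=0.0, noncr=0.0, death=1.0, cost=1234.5, qalys=0.25,
                       elapsed=0.9)
        res = run_cohort(
            phase,
            build_transition_matrix("imatinib", params),
            build_rewards("imatinib", params, toggles),
            horizon=10, discount_rate=0.05, toggles=toggles,
        )
        assert res.total_cost == pytest.approx(1234.5)
        assert res.total_qalys == pytest.approx(0.25)

    def test_occupancy_conserved_and_death_monotone(self, params, toggles):
        for arm in ("imatinib", "dasatinib"):
            trace = run_arm(arm, params, toggles).trace.table
            occ = trace[list(STATES)].to_numpy()
            assert np.abs(occ.sum(axis=1) - 1.0).max() < 1e-10
            death = trace["DEATH"].to_numpy()
            assert (np.diff(death) >= -1e-12).all()

    def test_discounted_accruals_not_above_undiscounted(self, params, toggles):
        trace = run_arm("imatinib", params, toggles).trace.table
        assert (trace["disc_cost"] <= trace["cost"] + 1e-9).all()
        assert (trace["disc_qalys"] <= trace["qalys"] + 1e-9).all()

    def test_total_qalys_bounded_by_time_alive(self, params, toggles):
        for arm in ("imatinib", "dasatinib"):
            res = run_arm(arm, params, toggles)
            assert res.total_qalys <= params.settings.horizon_years + res.phase.elapsed

    def test_totals_include_tree_phase(self, params, toggles):
        res = run_arm("dasatinib", params, toggles)
        assert res.total_cost >= res.phase.cost
        assert res.total_qalys >= res.phase.qalys

    def test_transplant_oneoff_charged_on_entry(self, params):
        """Removing the transplant cost lowers totals by the discounted
        transplanting mass times 250,000."""
        tg = StructureToggles()
        base = run_arm("imatinib", params, tg)
        free = run_arm("imatinib", params.with_values({"cost_transplant": 0.0}), tg)
        trace = base.trace.table
        # transplanting mass in cycle t = p_tx * (NONCR + RELAPSE mass at t-1)
        phase = base.phase
        prev_noncr = [phase.state_distribution["nonCR"]] + list(
            trace["NONCR"][:-1] + trace["RELAPSE"][:-1]
        )
        expected = sum(
            0.1 * m * 250000.0 * 1.05 ** -t
            for t, m in zip(trace["cycle"], prev_noncr)
        )
        assert base.total_cost - free.total_cost == pytest.approx(expected, rel=1e-9)

    def test_conservation_holds_under_random_parameter_draws(self, params):
        from tkicea.params import make_distribution

        rng = np.random.default_rng(42)
        ids = params.uncertain_ids()
        for _ in range(20):
            draw = {pid: float(make_distribution(params[pid]).sample(rng))
                    for pid in ids}
            ps = params.with_values(draw)
            for arm in ("imatinib", "dasatinib"):
                trace = run_arm(arm, ps).trace.table
                occ = trace[list(STATES)].to_numpy()
                assert np.abs(occ.sum(axis=1) - 1.0).max() < 1e-10


class TestRewards:
    def test_death_state_has_zero_rewards(self, params, toggles):
        costs, utils = build_rewards("imatinib", params, toggles)
        assert costs[IDX["DEATH"]] == 0.0 and utils[IDX["DEATH"]] == 0.0

    def test_maintenance_drug_toggle(self, params):
        with_drug, _ = build_rewards("imatinib", params,
                                     StructureToggles(drug_in_maintenance=True))
        without, _ = build_rewards("imatinib", params,
                                   StructureToggles(drug_in_maintenance=False))
        assert with_drug[IDX["CR"]] - without[IDX["CR"]] == pytest.approx(104857.2)

    def test_post_transplant_utility_split(self, params, toggles):
        _, utils = build_rewards("dasatinib", params, toggles)
        assert utils[IDX["HSCT_CR1"]] == pytest.approx(0.80)
        assert utils[IDX["HSCT_CR5"]] == pytest.approx(0.80)
        assert utils[IDX["HSCT_CR_LATE"]] == pytest.approx(0.86)
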