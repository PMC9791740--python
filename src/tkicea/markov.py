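"""Annual-cycle Markov cohort model of the maintenance period.

After intensive chemotherapy the cohort enters a 10-year Markov simulation
over maintenance CR, non-CR, relapse, post-transplant and death states, with
one-year cycles.  Non-CR and relapsed patients may receive hematopoietic stem
cell transplantation (HSCT); a successful transplant enters post-transplant
CR, a failed one the post-transplant failure state.  Post-transplant CR is a
tunnel: utility 0.80 for the first five years after transplantation and 0.86
thereafter, so the CR-after-HSCT state is expanded internally into five
yearly tunnel states plus a "late" state.  Death is absorbing with zero cost
and zero utility.

Costs and QALYs are accrued per cycle and discounted at the annual rate
``(1+r)^-t``.  By default rewards are valued on the post-transition occupancy
(end-of-cycle convention) with no half-cycle correction; both choices are
structural toggles resolved by calibration.  The one-off transplantation cost
is charged to the transplanting mass in the cycle the transplant occurs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ParameterSet
from .tree import ArmModel, PhaseOutcome, StructureToggles, run_decision_tree

#: internal (expanded) state order; HSCT_CR1..5 are the post-transplant CR
#: tunnel years, HSCT_CR_LATE the 6th year onward
STATES = (
    "CR",
    "NONCR",
    "RELAPSE",
    "HSCT_CR1",
    "HSCT_CR2",
    "HSCT_CR3",
    "HSCT_CR4",
    "HSCT_CR5",
    "HSCT_CR_LATE",
    "HSCT_FAIL",
    "DEATH",
)
IDX = {s: i for i, s in enumerate(STATES)}
N_STATES = len(STATES)

_ROW_TOL = 1e-9


class TransitionError(ValueError):
    """Raised when a transition row is not a probability vector."""


@dataclass(frozen=True)
class TransitionMatrix:
    """One-cycle transition matrix plus the transplant entry-cost rule."""

    arm: str
    matrix: np.ndarray  # (N_STATES, N_STATES)
    p_transplant: float  # per-cycle HSCT probability from NONCR/RELAPSE
    transplant_cost: float  # one-off CNY charged on HSCT entry

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (N_STATES, N_STATES):
            raise TransitionError(f"matrix shape {m.shape}")
        if (m < -1e-15).any() or (m > 1 + 1e-12).any():
            raise TransitionError("transition probabilities outside [0, 1]")
        rows = m.sum(axis=1)
        if np.abs(rows - 1.0).max() > _ROW_TOL:
            bad = STATES[int(np.abs(rows - 1.0).argmax())]
            raise TransitionError(f"row {bad} sums to {rows[IDX[bad]]:.12f}")
        death = np.zeros(N_STATES)
        death[IDX["DEATH"]] = 1.0
        if not np.allclose(m[IDX["DEATH"]], death):
            raise TransitionError("DEATH row must be the identity row")


def build_transition_matrix(arm: str, params: ParameterSet) -> TransitionMatrix:
    """Assemble the annual transition matrix for one arm.

    Maintenance relapse/mortality rows are arm-specific; transplantation and
    post-transplant rows are shared.  Competing per-cycle events from
    NONCR/RELAPSE (death, transplantation, stay) are treated as mutually
    exclusive; a negative remainder anywhere raises a validation error.
    """
    pfx = "im" if arm == "imatinib" else "da"
    if arm not in ("imatinib", "dasatinib"):
        raise ValueError(f"unknown arm {arm!r}")

    p_rel = params.value(f"{pfx}_relapse_maint")
    p_die_cr = params.value(f"{pfx}_death_cr_maint")
    p_die_noncr = params.value("death_noncr_maint")
    p_tx = params.value("p_transplant")
    p_tx_ok = params.value("p_transplant_success")
    p_rel_hsct = params.value("p_relapse_post_hsct")
    p_die_hsct_cr = params.value("p_death_cr_post_hsct")
    p_die_hsct_fail = params.value("p_death_fail_post_hsct")

    m = np.zeros((N_STATES, N_STATES))

    stay_cr = 1.0 - p_rel - p_die_cr
    if stay_cr < 0:
        raise TransitionError(f"{arm}: CR relapse+death exceed 1")
    m[IDX["CR"], IDX["RELAPSE"]] = p_rel
    m[IDX["CR"], IDX["DEATH"]] = p_die_cr
    m[IDX["CR"], IDX["CR"]] = stay_cr

    stay_noncr = 1.0 - p_die_noncr - p_tx
    if stay_noncr < 0:
        raise TransitionError("non-CR death+transplant exceed 1")
    for s in ("NONCR", "RELAPSE"):
        m[IDX[s], IDX["HSCT_CR1"]] = p_tx * p_tx_ok
        m[IDX[s], IDX["HSCT_FAIL"]] = p_tx * (1.0 - p_tx_ok)
        m[IDX[s], IDX["DEATH"]] = p_die_noncr
        m[IDX[s], IDX[s]] = stay_noncr

    stay_hsct_cr = 1.0 - p_rel_hsct - p_die_hsct_cr
    if stay_hsct_cr < 0:
        raise TransitionError("post-HSCT CR relapse+death exceed 1")
    hsct_chain = ["HSCT_CR1", "HSCT_CR2", "HSCT_CR3", "HSCT_CR4", "HSCT_CR5",
                  "HSCT_CR_LATE"]
    for i, s in enumerate(hsct_chain[:-1]):
        m[IDX[s], IDX["HSCT_FAIL"]] = p_rel_hsct
        m[IDX[s], IDX["DEATH"]] = p_die_hsct_cr
        m[IDX[s], IDX[hsct_chain[i + 1]]] = stay_hsct_cr
    s = "HSCT_CR_LATE"
    m[IDX[s], IDX["HSCT_FAIL"]] = p_rel_hsct
    m[IDX[s], IDX["DEATH"]] = p_die_hsct_cr
    m[IDX[s], IDX[s]] = stay_hsct_cr

    m[IDX["HSCT_FAIL"], IDX["DEATH"]] = p_die_hsct_fail
    m[IDX["HSCT_FAIL"], IDX["HSCT_FAIL"]] = 1.0 - p_die_hsct_fail

    m[IDX["DEATH"], IDX["DEATH"]] = 1.0

    return TransitionMatrix(
        arm=arm,
        matrix=m,
        p_transplant=p_tx,
        transplant_cost=params.value("cost_transplant"),
    )


def build_rewards(
    arm: str, params: ParameterSet, toggles: StructureToggles = StructureToggles()
) -> tuple[np.ndarray, np.ndarray]:
    """Annual (cost, utility) vectors over the internal state order.

    With ``drug_in_maintenance`` the arm's annual TKI cost is added to the CR
    maintenance state's other costs (maintenance therapy continues the TKI).
    """
    drug = params.value("im_drug_cost" if arm == "imatinib" else "da_drug_cost")
    cr_cost = params.value("cost_cr_maint")
    if toggles.drug_in_maintenance:
        cr_cost += drug
    noncr_cost = params.value("cost_noncr_maint")
    hsct_cr_cost = params.value("cost_cr_post_hsct")
    fail_cost = params.value("cost_fail_post_hsct")

    costs = np.zeros(N_STATES)
    utils = np.zeros(N_STATES)
    costs[IDX["CR"]] = cr_cost
    utils[IDX["CR"]] = params.value("u_cr")
    for s in ("NONCR", "RELAPSE"):
        costs[IDX[s]] = noncr_cost
        utils[IDX[s]] = params.value("u_noncr")
    for s in ("HSCT_CR1", "HSCT_CR2", "HSCT_CR3", "HSCT_CR4", "HSCT_CR5"):
        costs[IDX[s]] = hsct_cr_cost
        utils[IDX[s]] = params.value("u_hsct_cr_early")
    costs[IDX["HSCT_CR_LATE"]] = hsct_cr_cost
    utils[IDX["HSCT_CR_LATE"]] = params.value("u_hsct_cr_late")
    costs[IDX["HSCT_FAIL"]] = fail_cost
    utils[IDX["HSCT_FAIL"]] = params.value("u_hsct_fail")
    # DEATH: zero cost, zero utility
    return costs, utils


def discount_factor(t: float, r: float) -> float:
    """Annual compound discount factor ``(1+r)^-t``; ``t=0`` gives 1."""
    if r < 0:
        raise ValueError("discount rate must be non-negative")
    if t < 0:
        raise ValueError("cycle index must be non-negative")
    return (1.0 + r) ** (-t)


@dataclass(frozen=True)
class MarkovTrace:
    """Per-cycle occupancy and accruals; ``table`` has one row per cycle."""

    table: pd.DataFrame
    total_cost: float  # discounted Markov-phase cost
    total_qalys: float  # discounted Markov-phase QALYs


@dataclass(frozen=True)
class ArmResult:
    """Full-arm totals: decision tree plus Markov phase, discounted."""

    arm: str
    total_cost: float
    total_qalys: float
    phase: PhaseOutcome
    trace: MarkovTrace


def initial_occupancy(phase: PhaseOutcome) -> np.ndarray:
    occ = np.zeros(N_STATES)
    occ[IDX["CR"]] = phase.state_distribution["CR"]
    occ[IDX["NONCR"]] = phase.state_distribution["nonCR"]
    occ[IDX["DEATH"]] = phase.state_distribution["death"]
    return occ


def run_cohort(
    initial: PhaseOutcome,
    matrix: TransitionMatrix,
    rewards: tuple[np.ndarray, np.ndarray],
    horizon: int,
    discount_rate: float,
    toggles: StructureToggles = StructureToggles(),
) -> ArmResult:
    """Propagate the cohort ``horizon`` cycles and accrue discounted rewards.

    Reward timing follows the toggles: end-of-cycle (default) values the
    post-transition occupancy at ``(1+r)^-t``; start-of-cycle values the
    pre-transition occupancy at ``(1+r)^-(t-1)``; the half-cycle correction
    averages the two.  The one-off transplantation cost is charged to the
    newly transplanted mass under the same timing convention.
    """
    costs, utils = rewards
    occ = initial_occupancy(initial)
    if abs(occ.sum() - 1.0) > 1e-10:
        raise ValueError("initial occupancy does not sum to 1")

    rows = []
    tot_cost = 0.0
    tot_qaly = 0.0
    for t in range(1, int(horizon) + 1):
        pre = occ
        post = pre @ matrix.matrix
        if abs(post.sum() - 1.0) > 1e-8:
            raise TransitionError(f"occupancy drift at cycle {t}: {post.sum()!r}")

        tx_mass = (pre[IDX["NONCR"]] + pre[IDX["RELAPSE"]]) * matrix.p_transplant
        oneoff = tx_mass * matrix.transplant_cost

        d_end = discount_factor(t, discount_rate)
        d_start = discount_factor(t - 1, discount_rate)

        end_cost = float(post @ costs) + oneoff
        end_qaly = float(post @ utils)
        start_cost = float(pre @ costs) + oneoff
        start_qaly = float(pre @ utils)

        if toggles.half_cycle:
            cyc_cost = 0.5 * (start_cost + end_cost)
            cyc_qaly = 0.5 * (start_qaly + end_qaly)
            dcost = 0.5 * (start_cost * d_start + end_cost * d_end)
            dqaly = 0.5 * (start_qaly * d_start + end_qaly * d_end)
        elif toggles.start_cycle_rewards:
            cyc_cost, cyc_qaly = start_cost, start_qaly
            dcost, dqaly = start_cost * d_start, start_qaly * d_start
        else:
            cyc_cost, cyc_qaly = end_cost, end_qaly
            dcost, dqaly = end_cost * d_end, end_qaly * d_end

        tot_cost += dcost
        tot_qaly += dqaly
        rows.append(
            {"cycle": t, **{s: post[IDX[s]] for s in STATES},
             "cost": cyc_cost, "qalys": cyc_qaly,
             "disc_cost": dcost, "disc_qalys": dqaly}
        )
        occ = post

    trace = MarkovTrace(table=pd.DataFrame(rows), total_cost=tot_cost, total_qalys=tot_qaly)
    return ArmResult(
        arm=matrix.arm,
        total_cost=initial.cost + tot_cost,
        total_qalys=initial.qalys + tot_qaly,
        phase=initial,
        trace=trace,
    )


def run_arm(
    arm: str,
    params: ParameterSet,
    toggles: StructureToggles = StructureToggles(),
) -> ArmResult:
    """Decision tree followed by the Markov cohort model for one arm."""
    phase = run_decision_tree(arm, params, toggles)
    matrix = build_transition_matrix(arm, params)
    rewards = build_rewards(arm, params, toggles)
    return run_cohort(
        phase, matrix, rewards,
        horizon=params.settings.horizon_years,
        discount_rate=params.settings.discount_rate,
        toggles=toggles,
    )
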