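"""Patient-level synthetic cohort generator and microsimulation oracle.

Emulates the retrospective cohort behind the decision-tree probabilities:
individual patients walk through induction, intensive chemotherapy, and the
annual Markov maintenance cycles under exactly the same probabilities, reward
conventions, and structural toggles as the cohort (expected-value) model.
The generator serves two purposes:

* a microsimulation oracle — at large ``n`` the empirical state occupancy and
  the per-patient mean discounted cost/QALYs must agree with the cohort
  engine's trace and totals (law of large numbers);
* parameter-recovery experiments — transition probabilities re-estimated from
  small samples (the study cohort was 32 patients: 14 imatinib, 18 dasatinib)
  with exact binomial confidence intervals.

The default cohort mirrors the study: n=14 for imatinib, n=18 for dasatinib.
No covariates are modelled; the economic model uses none.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .markov import IDX, N_STATES, STATES, build_rewards, build_transition_matrix, discount_factor
from .params import ParameterSet, exact_binomial_ci, load_parameters
from .tree import ArmModel, StructureToggles, end_of_intensive_cr, run_decision_tree

#: study cohort sizes per arm
DEFAULT_N = {"imatinib": 14, "dasatinib": 18}

#: state groups used when re-estimating transition probabilities (the
#: post-transplant CR tunnel years share one transition law)
_GROUP = {
    **{s: s for s in ("CR", "NONCR", "RELAPSE", "HSCT_FAIL", "DEATH")},
    **{s: "HSCT_CR" for s in
       ("HSCT_CR1", "HSCT_CR2", "HSCT_CR3", "HSCT_CR4", "HSCT_CR5", "HSCT_CR_LATE")},
}


@dataclass(frozen=True)
class PatientTrajectory:
    """One simulated patient's path and discounted accruals."""

    patient_id: int
    arm: str
    induction_state: str  # CR | nonCR after induction
    intensive_state: str  # CR | nonCR at end of intensive chemotherapy
    states: tuple[str, ...]  # Markov state at the end of each cycle
    transplant_cycle: int | None
    death_cycle: int | None
    cost: float
    qalys: float


@dataclass(frozen=True)
class SimulatedCohort:
    """Vectorized container of simulated trajectories for one arm."""

    arm: str
    seed: int
    horizon: int
    induction_cr: np.ndarray  # (n,) bool
    state_codes: np.ndarray  # (n, horizon+1) int8, col 0 = post-intensive state
    transplant_cycle: np.ndarray  # (n,) int, -1 if never
    death_cycle: np.ndarray  # (n,) int, -1 if never
    cost: np.ndarray  # (n,) discounted total incl. tree phase
    qalys: np.ndarray  # (n,)

    def __len__(self) -> int:
        return self.state_codes.shape[0]

    def __iter__(self) -> Iterator[PatientTrajectory]:
        for i in range(len(self)):
            tx = int(self.transplant_cycle[i])
            dth = int(self.death_cycle[i])
            yield PatientTrajectory(
                patient_id=i,
                arm=self.arm,
                induction_state="CR" if self.induction_cr[i] else "nonCR",
                intensive_state=STATES[self.state_codes[i, 0]]
                if STATES[self.state_codes[i, 0]] != "NONCR" else "nonCR",
                states=tuple(STATES[c] for c in self.state_codes[i, 1:]),
                transplant_cycle=tx if tx >= 0 else None,
                death_cycle=dth if dth >= 0 else None,
                cost=float(self.cost[i]),
                qalys=float(self.qalys[i]),
            )

    def occupancy(self) -> pd.DataFrame:
        """Empirical per-cycle state occupancy (fractions), cycles 1..horizon."""
        n = len(self)
        rows = []
        for t in range(1, self.horizon + 1):
            counts = np.bincount(self.state_codes[:, t], minlength=N_STATES)
            rows.append({"cycle": t, **{s: counts[IDX[s]] / n for s in STATES}})
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        """One row per patient-cycle, suitable for CSV export."""
        rows = []
        for p in self:
            rows.append({"patient_id": p.patient_id, "arm": p.arm, "cycle": 0,
                         "state": p.intensive_state})
            for t, s in enumerate(p.states, start=1):
                rows.append({"patient_id": p.patient_id, "arm": p.arm,
                             "cycle": t, "state": s})
        return pd.DataFrame(rows)


def simulate_patients(
    arm: str,
    params: ParameterSet | None = None,
    n: int | None = None,
    seed: int = 0,
    toggles: StructureToggles = StructureToggles(),
) -> SimulatedCohort:
    """Simulate ``n`` patients of one arm through tree and Markov phases.

    Uses the same transition matrix, rewards, discounting, and reward-timing
    conventions as :func:`tkicea.markov.run_cohort`, so empirical averages
    converge to the cohort-model trace.  Reproducible under ``seed``.
    """
    if params is None:
        params = load_parameters()
    if n is None:
        n = DEFAULT_N[arm]
    if n < 1:
        raise ValueError("n must be >= 1")

    am = ArmModel.from_params(arm, params)
    phase = run_decision_tree(am, params, toggles)
    matrix = build_transition_matrix(arm, params)
    costs, utils = build_rewards(arm, params, toggles)
    horizon = int(params.settings.horizon_years)
    r = params.settings.discount_rate

    rng = np.random.default_rng(seed)

    # decision tree: induction response, then end-of-intensive response
    induction_cr = rng.random(n) < 1.0 - am.p_noncr_induction
    if toggles.group_level_cr:
        # group-level CR rate applied marginally (matches the cohort model)
        end_cr = rng.random(n) < end_of_intensive_cr(am, toggles)
    else:
        u = rng.random(n)
        end_cr = np.where(
            induction_cr, u < am.p_cr_stay_intensive, u < am.p_cr_conversion_intensive
        )

    state = np.where(end_cr, IDX["CR"], IDX["NONCR"]).astype(np.int8)
    state_codes = np.empty((n, horizon + 1), dtype=np.int8)
    state_codes[:, 0] = state

    cum = np.cumsum(matrix.matrix, axis=1)
    tx_targets = (IDX["HSCT_CR1"], IDX["HSCT_FAIL"])
    tx_sources = (IDX["NONCR"], IDX["RELAPSE"])

    transplant_cycle = np.full(n, -1, dtype=int)
    death_cycle = np.full(n, -1, dtype=int)
    cost_tot = np.full(n, phase.cost)
    qaly_tot = np.full(n, phase.qalys)

    for t in range(1, horizon + 1):
        pre = state
        u = rng.random(n)
        post = (u[:, None] < cum[pre]).argmax(axis=1).astype(np.int8)

        newly_tx = (
            np.isin(pre, tx_sources) & np.isin(post, tx_targets) & (transplant_cycle < 0)
        )
        transplant_cycle[newly_tx] = t
        newly_dead = (post == IDX["DEATH"]) & (death_cycle < 0)
        death_cycle[newly_dead] = t

        oneoff = np.where(newly_tx, matrix.transplant_cost, 0.0)
        d_end = discount_factor(t, r)
        d_start = discount_factor(t - 1, r)
        end_cost = costs[post] + oneoff
        end_qaly = utils[post]
        start_cost = costs[pre] + oneoff
        start_qaly = utils[pre]

        if toggles.half_cycle:
            cost_tot += 0.5 * (start_cost * d_start + end_cost * d_end)
            qaly_tot += 0.5 * (start_qaly * d_start + end_qaly * d_end)
        elif toggles.start_cycle_rewards:
            cost_tot += start_cost * d_start
            qaly_tot += start_qaly * d_start
        else:
            cost_tot += end_cost * d_end
            qaly_tot += end_qaly * d_end

        state_codes[:, t] = post
        state = post

    return SimulatedCohort(
        arm=arm, seed=seed, horizon=horizon,
        induction_cr=induction_cr, state_codes=state_codes,
        transplant_cycle=transplant_cycle, death_cycle=death_cycle,
        cost=cost_tot, qalys=qaly_tot,
    )


def estimate_transition_probs(cohort: SimulatedCohort) -> pd.DataFrame:
    """Maximum-likelihood transition estimates with exact 95% intervals.

    Tree transitions are estimated from the phase outcomes; Markov transitions
    from all observed (state, next state) pairs, pooling the post-transplant
    CR tunnel years (they share one transition law).  Rows with zero patients
    at risk are flagged (``estimate`` is NaN) rather than dropped.
    """
    rows = []

    def add(name: str, events: int, at_risk: int) -> None:
        if at_risk == 0:
            rows.append({"transition": name, "events": 0, "at_risk": 0,
                         "estimate": np.nan, "ci_low": np.nan, "ci_high": np.nan})
            return
        lo, hi = exact_binomial_ci(events, at_risk)
        rows.append({"transition": name, "events": events, "at_risk": at_risk,
                     "estimate": events / at_risk, "ci_low": lo, "ci_high": hi})

    n = len(cohort)
    n_cr_ind = int(cohort.induction_cr.sum())
    add("noncr_after_induction", n - n_cr_ind, n)
    end_cr = cohort.state_codes[:, 0] == IDX["CR"]
    add("cr_of_noncr_intensive",
        int((end_cr & ~cohort.induction_cr).sum()), n - n_cr_ind)
    add("cr_of_cr_intensive", int((end_cr & cohort.induction_cr).sum()), n_cr_ind)

    # transitions allowed by the model graph, per pooled state group
    graph = {
        "CR": ("CR", "RELAPSE", "DEATH"),
        "NONCR": ("NONCR", "HSCT_CR", "HSCT_FAIL", "DEATH"),
        "RELAPSE": ("RELAPSE", "HSCT_CR", "HSCT_FAIL", "DEATH"),
        "HSCT_CR": ("HSCT_CR", "HSCT_FAIL", "DEATH"),
        "HSCT_FAIL": ("HSCT_FAIL", "DEATH"),
    }
    groups = np.array([_GROUP[s] for s in STATES])
    pre = cohort.state_codes[:, :-1].ravel()
    post = cohort.state_codes[:, 1:].ravel()
    for g_from, targets in graph.items():
        mask = groups[pre] == g_from
        at_risk = int(mask.sum())
        for g_to in targets:
            events = int((groups[post[mask]] == g_to).sum())
            add(f"{g_from}->{g_to}", events, at_risk)

    return pd.DataFrame(rows)


def microsim_value(cohort: SimulatedCohort) -> dict[str, float]:
    """Mean discounted cost and QALYs per patient with standard errors."""
    n = len(cohort)
    return {
        "mean_cost": float(cohort.cost.mean()),
        "se_cost": float(cohort.cost.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        "mean_qalys": float(cohort.qalys.mean()),
        "se_qalys": float(cohort.qalys.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        "n": n,
    }
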