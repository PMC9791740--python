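"""Decision-tree phase: induction and intensive chemotherapy.

Both arms pass through a short induction phase (~4 weeks) and an intensive
chemotherapy phase (~44 weeks).  At the end of intensive chemotherapy every
patient is in complete response (CR), non-CR, or dead; that distribution
seeds the Markov maintenance model.  No induction/intensive mortality is
parameterized, so the tree death probability is 0.

Several structural choices are not pinned down by the published totals alone;
they are exposed as :class:`StructureToggles` and selected by calibration
(:func:`tkicea.cea.calibrate_structure`):

* ``group_level_cr`` — dasatinib end-of-intensive CR: compose the two tree
  probabilities (0.167 + 0.833*0.875 = 0.8959) or use the group-level 0.875
  directly.
* ``drug_proration_in_tree`` — TKI cost accrued over the actual phase
  durations (default) or as a full-year charge.
* ``prorate_other_costs`` — phase "other costs" as per-episode lump sums
  (default; they are admission expense totals) or prorated per year.
* ``discount_tree`` — tree accruals undiscounted (they fall in year 0,
  default) or discounted continuously from time zero.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

from .params import ParameterSet

ARMS = ("imatinib", "dasatinib")


@dataclass(frozen=True)
class StructureToggles:
    """Binary structural switches left open by the published model description."""

    group_level_cr: bool = False
    drug_in_maintenance: bool = True
    drug_proration_in_tree: bool = True
    half_cycle: bool = False
    start_cycle_rewards: bool = False
    discount_tree: bool = False
    prorate_other_costs: bool = False

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))

    def as_dict(self) -> dict[str, bool]:
        return {name: getattr(self, name) for name in self.field_names()}


@dataclass(frozen=True)
class ArmModel:
    """Resolved per-arm inputs: tree probabilities, durations, drug cost."""

    arm: str
    p_noncr_induction: float
    p_cr_conversion_intensive: float  # P(CR at end | non-CR after induction)
    p_cr_stay_intensive: float  # P(CR at end | CR after induction)
    group_cr_rate: float  # group-level end-of-intensive CR rate
    dur_induction: float
    dur_intensive: float
    drug_cost: float
    other_cost_induction: float
    other_cost_intensive: float

    @classmethod
    def from_params(cls, arm: str, params: ParameterSet) -> "ArmModel":
        if arm not in ARMS:
            raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
        if arm == "imatinib":
            # the source reports group-level non-CR proportions; with induction
            # CR = 0 the intensive conversion equals 1 - non-CR proportion
            p_noncr_ind = params.value("im_noncr_induction")
            conv = 1.0 - params.value("im_noncr_intensive")
            return cls(
                arm=arm,
                p_noncr_induction=p_noncr_ind,
                p_cr_conversion_intensive=conv,
                p_cr_stay_intensive=1.0,
                group_cr_rate=conv,
                dur_induction=params.value("im_dur_induction"),
                dur_intensive=params.value("im_dur_intensive"),
                drug_cost=params.value("im_drug_cost"),
                other_cost_induction=params.value("im_cost_induction"),
                other_cost_intensive=params.value("im_cost_intensive"),
            )
        return cls(
            arm=arm,
            p_noncr_induction=params.value("da_noncr_induction"),
            p_cr_conversion_intensive=params.value("da_cr_noncr_intensive"),
            p_cr_stay_intensive=params.value("da_cr_cr_intensive"),
            group_cr_rate=params.value("da_cr_noncr_intensive"),
            dur_induction=params.value("da_dur_induction"),
            dur_intensive=params.value("da_dur_intensive"),
            drug_cost=params.value("da_drug_cost"),
            other_cost_induction=params.value("da_cost_induction"),
            other_cost_intensive=params.value("da_cost_intensive"),
        )

    @property
    def elapsed(self) -> float:
        return self.dur_induction + self.dur_intensive


@dataclass(frozen=True)
class PhaseOutcome:
    """End-of-intensive-phase state distribution plus phase accruals."""

    state_distribution: dict[str, float]  # {CR, nonCR, death}
    cost: float
    qalys: float
    elapsed: float

    def __post_init__(self) -> None:
        total = sum(self.state_distribution.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"phase state distribution sums to {total}, not 1")
        if any(not 0.0 <= p <= 1.0 for p in self.state_distribution.values()):
            raise ValueError("phase state probabilities outside [0, 1]")


def end_of_intensive_cr(arm_model: ArmModel, toggles: StructureToggles) -> float:
    """Probability of CR at the end of intensive chemotherapy."""
    if toggles.group_level_cr:
        return arm_model.group_cr_rate
    cr_ind = 1.0 - arm_model.p_noncr_induction
    return (
        cr_ind * arm_model.p_cr_stay_intensive
        + arm_model.p_noncr_induction * arm_model.p_cr_conversion_intensive
    )


def run_decision_tree(
    arm: str | ArmModel,
    params: ParameterSet,
    toggles: StructureToggles = StructureToggles(),
) -> PhaseOutcome:
    """Run both tree phases for one arm.

    Returns the end-of-phase state distribution, the phase cost (other costs
    plus TKI drug cost per the accrual toggles) and phase QALYs (elapsed time
    weighted by the on-treatment utility, taken as the non-CR utility since
    patients are under active chemotherapy throughout).
    """
    am = arm if isinstance(arm, ArmModel) else ArmModel.from_params(arm, params)

    p_cr = end_of_intensive_cr(am, toggles)
    dist = {"CR": p_cr, "nonCR": 1.0 - p_cr, "death": 0.0}

    drug_exposure = am.elapsed if toggles.drug_proration_in_tree else 1.0
    other = am.other_cost_induction + am.other_cost_intensive
    if toggles.prorate_other_costs:
        other = (
            am.other_cost_induction * am.dur_induction
            + am.other_cost_intensive * am.dur_intensive
        )
    cost = other + am.drug_cost * drug_exposure

    qalys = am.elapsed * params.value("u_noncr")

    if toggles.discount_tree:
        r = params.settings.discount_rate
        f = (1.0 + r) ** (-am.elapsed)
        cost *= f
        qalys *= f

    return PhaseOutcome(state_distribution=dist, cost=cost, qalys=qalys, elapsed=am.elapsed)
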