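"""One-way/tornado sensitivity, Monte-Carlo PSA, ICE scatter data, and CEAC.

One-way analysis re-runs the full pipeline with a single parameter at its
lower and upper plausible bound (everything else at base) and records the
incremental net monetary benefit (iNMB) at each; the tornado ranks parameters
by the resulting iNMB span.  The probabilistic sensitivity analysis (PSA)
draws every uncertain parameter independently from its fitted Beta/Gamma
distribution (costs Gamma, probabilities and utilities Beta), evaluates both
arms per draw with the *same* draw for arm-shared parameters, and records the
incremental (cost, effect) pair.  The cost-effectiveness acceptability curve
(CEAC) is the fraction of draws with positive net monetary benefit as a
function of the willingness-to-pay threshold.

The discount rate is varied one-way only (3%-8%), never sampled in the PSA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cea import CEAResult, run_base_case
from .params import ParameterSet, load_parameters, make_distribution
from .tree import StructureToggles

#: pseudo-parameter id for the one-way analysis of the discount rate
DISCOUNT_RATE_ID = "discount_rate"


@dataclass(frozen=True)
class TornadoEntry:
    """One-way iNMB swing of a single parameter."""

    param_id: str
    low: float
    high: float
    inmb_at_low: float
    inmb_at_high: float

    @property
    def span(self) -> float:
        return abs(self.inmb_at_high - self.inmb_at_low)


@dataclass(frozen=True)
class PSASample:
    """One Monte-Carlo draw's incremental cost and effect."""

    draw: int
    delta_cost: float
    delta_effect: float
    tag: str  # seed-derived reproducibility tag

    def nmb(self, wtp: float) -> float:
        return wtp * self.delta_effect - self.delta_cost


@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    probability_cost_effective: float


def _bounds(pid: str, params: ParameterSet) -> tuple[float, float]:
    if pid == DISCOUNT_RATE_ID:
        s = params.settings
        return s.discount_rate_low, s.discount_rate_high
    spec = params[pid]
    return spec.low, spec.high


def one_way(
    pid: str,
    params: ParameterSet | None = None,
    wtp: float | None = None,
    toggles: StructureToggles | None = None,
) -> TornadoEntry:
    """iNMB with ``pid`` at its lower and upper bound, all else at base."""
    if params is None:
        params = load_parameters()
    lo, hi = _bounds(pid, params)
    inmbs = []
    for v in (lo, hi):
        ps = params.with_values({pid: v})
        inmbs.append(run_base_case(ps, toggles, wtp)[2].inmb)
    return TornadoEntry(param_id=pid, low=lo, high=hi,
                        inmb_at_low=inmbs[0], inmb_at_high=inmbs[1])


def tornado(
    params: ParameterSet | None = None,
    wtp: float | None = None,
    toggles: StructureToggles | None = None,
    ids: Iterable[str] | None = None,
) -> list[TornadoEntry]:
    """One-way entries for every parameter with a range, sorted by span.

    Includes the discount rate (varied 3%-8%).  Ties are broken by parameter
    id so the ordering is independent of evaluation order.
    """
    if params is None:
        params = load_parameters()
    if ids is None:
        ids = params.uncertain_ids() + [DISCOUNT_RATE_ID]
    entries = [one_way(pid, params, wtp, toggles) for pid in ids]
    return sorted(entries, key=lambda e: (-e.span, e.param_id))


def run_psa(
    params: ParameterSet | None = None,
    n: int = 1000,
    seed: int = 0,
    toggles: StructureToggles | None = None,
    sd_rule: str = "range95",
) -> list[PSASample]:
    """Monte-Carlo PSA: ``n`` independent joint draws of all uncertain parameters.

    Distributions are fitted up front (so an invalid specification fails
    before any model run) and sampled in sorted-id order from a single
    generator, making the stream a pure function of ``seed``.
    """
    if params is None:
        params = load_parameters()
    if n < 1:
        raise ValueError("n must be >= 1")
    ids = params.uncertain_ids()
    dists = {pid: make_distribution(params[pid], sd_rule=sd_rule) for pid in ids}

    rng = np.random.default_rng(seed)
    draws = {pid: np.asarray(dists[pid].sample(rng, size=n)) for pid in ids}

    samples = []
    for d in range(n):
        ps = params.with_values({pid: float(draws[pid][d]) for pid in ids})
        _, _, cea = run_base_case(ps, toggles)
        samples.append(
            PSASample(draw=d, delta_cost=cea.delta_cost,
                      delta_effect=cea.delta_effect, tag=f"{seed}:{d}")
        )
    return samples


def probability_cost_effective(samples: Sequence[PSASample], wtp: float) -> float:
    """Fraction of PSA draws with positive net monetary benefit at ``wtp``."""
    if not samples:
        raise ValueError("no PSA samples")
    return sum(1 for s in samples if s.nmb(wtp) > 0) / len(samples)


def ceac(
    samples: Sequence[PSASample],
    wtp_grid: Sequence[float] | None = None,
) -> list[CEACPoint]:
    """Cost-effectiveness acceptability curve over a WTP grid."""
    if not samples:
        raise ValueError("no PSA samples")
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 200_001.0, 2_000.0)
    return [
        CEACPoint(wtp=float(w),
                  probability_cost_effective=probability_cost_effective(samples, float(w)))
        for w in wtp_grid
    ]


def psa_frame(samples: Sequence[PSASample]) -> pd.DataFrame:
    """PSA samples as a DataFrame (draw, delta_cost, delta_effect, tag)."""
    return pd.DataFrame(
        {"draw": [s.draw for s in samples],
         "delta_cost": [s.delta_cost for s in samples],
         "delta_effect": [s.delta_effect for s in samples],
         "tag": [s.tag for s in samples]}
    )
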