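"""Parameter registry, probability transforms, and sampling distributions.

Every model quantity — transition probabilities, annual state costs, the
one-off transplantation cost, phase durations, and health-state utilities —
lives in a single :class:`ParameterSet` loaded from a flat YAML document.
That registry is the single source of truth for the base case, the one-way
sensitivity analysis, and the probabilistic sensitivity analysis (PSA).

Uncertainty conventions
-----------------------
* Each parameter carries a plausible range ``(low, high)``.  Where the source
  gives none, default one-way bounds are generated at load time: +/-10% of the
  base value for transition probabilities and +/-20% for costs and utilities
  (clipped to the parameter's support).
* For the PSA, ranges are converted to a standard deviation under a
  configurable rule — ``range/3.92`` (the range read as a central 95%
  interval, the default) or ``range/4`` — and a Beta (probabilities,
  utilities) or Gamma (costs) distribution is fitted by method of moments so
  that its mean equals the base value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml
from scipy import stats

logger = logging.getLogger("tkicea")

FAMILIES = ("beta", "gamma", "fixed")
ROLES = ("transition", "cost", "utility", "duration", "setting")

#: ids every analysis in the package expects to resolve
REQUIRED_IDS = frozenset(
    {
        "im_noncr_induction", "im_noncr_intensive",
        "da_noncr_induction", "da_cr_cr_intensive", "da_cr_noncr_intensive",
        "im_relapse_maint", "im_death_cr_maint",
        "da_relapse_maint", "da_death_cr_maint",
        "death_noncr_maint", "p_transplant", "p_transplant_success",
        "p_relapse_post_hsct", "p_death_cr_post_hsct", "p_death_fail_post_hsct",
        "im_drug_cost", "im_cost_induction", "im_cost_intensive",
        "da_drug_cost", "da_cost_induction", "da_cost_intensive",
        "cost_cr_maint", "cost_noncr_maint", "cost_transplant",
        "cost_cr_post_hsct", "cost_fail_post_hsct",
        "im_dur_induction", "im_dur_intensive",
        "da_dur_induction", "da_dur_intensive",
        "u_cr", "u_noncr", "u_hsct_cr_early", "u_hsct_cr_late", "u_hsct_fail",
    }
)

# default one-way fluctuation where the source reports no range
DEFAULT_REL_RANGE = {"transition": 0.10, "cost": 0.20, "utility": 0.20}


class ParameterError(ValueError):
    """Raised when a parameter file is malformed or a value is out of support."""


@dataclass(frozen=True)
class ParameterSpec:
    """One registry entry: base value, plausible range, PSA family, role."""

    id: str
    base: float
    low: float
    high: float
    family: str  # beta | gamma | fixed
    role: str  # transition | cost | utility | duration | setting
    range_source: str = "reported"  # reported | default | fixed

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ParameterError(f"{self.id}: unknown family {self.family!r}")
        if self.role not in ROLES:
            raise ParameterError(f"{self.id}: unknown role {self.role!r}")
        if not (self.low <= self.base <= self.high):
            raise ParameterError(
                f"{self.id}: range ({self.low}, {self.high}) does not bracket "
                f"base {self.base}"
            )
        if self.role in ("transition", "utility"):
            if not (0.0 <= self.low and self.high <= 1.0):
                raise ParameterError(
                    f"{self.id}: probability/utility outside [0, 1]: "
                    f"base={self.base}, range=({self.low}, {self.high})"
                )
        elif self.low < 0.0:
            raise ParameterError(f"{self.id}: negative value for role {self.role}")

    @property
    def is_uncertain(self) -> bool:
        return self.family != "fixed" and self.high > self.low


@dataclass(frozen=True)
class Settings:
    """Analysis-wide settings shared by every module."""

    horizon_years: int = 10
    discount_rate: float = 0.05
    discount_rate_low: float = 0.03
    discount_rate_high: float = 0.08
    wtp: float = 70892.0
    body_surface_area: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 <= self.discount_rate <= 1.0):
            raise ParameterError(f"discount_rate {self.discount_rate} outside [0, 1]")
        if int(self.horizon_years) != self.horizon_years or self.horizon_years < 1:
            raise ParameterError(f"horizon_years must be an integer >= 1")


@dataclass(frozen=True)
class ParameterSet:
    """Validated registry of :class:`ParameterSpec` plus analysis settings."""

    entries: Mapping[str, ParameterSpec]
    settings: Settings = field(default_factory=Settings)

    def __getitem__(self, pid: str) -> ParameterSpec:
        try:
            return self.entries[pid]
        except KeyError:
            raise ParameterError(f"unknown parameter id {pid!r}") from None

    def value(self, pid: str) -> float:
        return self[pid].base

    def ids(self) -> Iterable[str]:
        return self.entries.keys()

    def uncertain_ids(self) -> list[str]:
        """Ids with a non-degenerate range, in deterministic (sorted) order."""
        return sorted(pid for pid, sp in self.entries.items() if sp.is_uncertain)

    def with_values(self, overrides: Mapping[str, float]) -> "ParameterSet":
        """New ParameterSet with base values (or settings) replaced.

        Keys matching :class:`Settings` fields (``discount_rate``,
        ``horizon_years``, ``wtp``) update the settings; all other keys must
        name existing parameters.  Ranges are widened minimally when the new
        base falls outside the old range (the range is a sampling aid, the
        base value is authoritative).
        """
        entries = dict(self.entries)
        settings = self.settings
        for pid, val in overrides.items():
            if pid in ("discount_rate", "horizon_years", "wtp"):
                settings = replace(settings, **{pid: val})
                continue
            spec = self[pid]
            entries[pid] = replace(
                spec, base=float(val),
                low=min(spec.low, float(val)), high=max(spec.high, float(val)),
            )
        return ParameterSet(entries=entries, settings=settings)


# ---------------------------------------------------------------------------
# loading

def _fill_default_range(pid, base, low, high, family, role):
    """Apply the default one-way fluctuation where no range is reported."""
    if low is not None and high is not None:
        return float(low), float(high), "reported"
    if family == "fixed" or role == "duration":
        return base, base, "fixed"
    rel = DEFAULT_REL_RANGE[role]
    lo, hi = base * (1 - rel), base * (1 + rel)
    if role in ("transition", "utility"):
        lo, hi = max(lo, 0.0), min(hi, 1.0)
    return lo, hi, "default"


def load_parameters(source: str | Path | None = None) -> ParameterSet:
    """Load and validate a parameter registry from a YAML document.

    With ``source=None`` the bundled base-case table is used.  Raises
    :class:`ParameterError` naming the offending id when a required parameter
    is missing, duplicated, or out of support.
    """
    if source is None:
        text = resources.files("tkicea.data").joinpath("parameters.yaml").read_text()
    else:
        text = Path(source).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "parameters" not in doc:
        raise ParameterError("parameter file must contain a 'parameters' list")

    entries: dict[str, ParameterSpec] = {}
    for rec in doc["parameters"]:
        pid = rec.get("id")
        if pid is None:
            raise ParameterError("parameter record without an 'id'")
        if pid in entries:
            raise ParameterError(f"duplicate parameter id {pid!r}")
        base = float(rec["base"])
        family = rec.get("family", "fixed")
        role = rec.get("role", "setting")
        low, high, src = _fill_default_range(
            pid, base, rec.get("low"), rec.get("high"), family, role
        )
        entries[pid] = ParameterSpec(
            id=pid, base=base, low=low, high=high,
            family=family, role=role, range_source=src,
        )

    missing = REQUIRED_IDS - entries.keys()
    if missing:
        raise ParameterError(f"missing required parameter id(s): {sorted(missing)}")

    settings = Settings(**(doc.get("settings") or {}))
    return ParameterSet(entries=entries, settings=settings)


# ---------------------------------------------------------------------------
# probability transforms

def annual_from_cumulative(p_cum: float, years: float) -> float:
    """Annual transition probability implied by a cumulative one over ``years``.

    Uses the constant-rate relation ``p = 1 - (1 - P)**(1/T)``, the standard
    conversion between a T-year cumulative incidence and a per-cycle
    probability under an exponential hazard.
    """
    if not 0.0 <= p_cum <= 1.0:
        raise ValueError(f"cumulative probability {p_cum} outside [0, 1]")
    if years <= 0:
        raise ValueError("years must be positive")
    if p_cum == 1.0:
        return 1.0
    return -math.expm1(math.log1p(-p_cum) / years)


def cumulative_from_annual(p_annual: float, years: float) -> float:
    """Cumulative probability over ``years`` implied by an annual one."""
    if not 0.0 <= p_annual <= 1.0:
        raise ValueError(f"annual probability {p_annual} outside [0, 1]")
    if years <= 0:
        raise ValueError("years must be positive")
    if p_annual == 1.0:
        return 1.0
    return -math.expm1(years * math.log1p(-p_annual))


# ---------------------------------------------------------------------------
# PSA distributions

@dataclass(frozen=True)
class Distribution:
    """Sampling distribution for one parameter, fitted by method of moments.

    ``family='fixed'`` (or a degenerate range/boundary mean) is a point mass.
    """

    family: str
    mean: float
    sd: float
    a: float = 0.0  # beta alpha / gamma shape
    b: float = 0.0  # beta beta / gamma scale

    def sample(self, rng: np.random.Generator, size: int | None = None):
        if self.family == "fixed":
            return self.mean if size is None else np.full(size, self.mean)
        if self.family == "beta":
            return rng.beta(self.a, self.b, size=size)
        return rng.gamma(self.a, self.b, size=size)


def make_distribution(spec: ParameterSpec, sd_rule: str = "range95") -> Distribution:
    """Fit the PSA distribution for one parameter.

    ``sd_rule`` maps the plausible range to a standard deviation:
    ``"range95"`` -> (high-low)/3.92 (range read as a central 95% interval),
    ``"range4"`` -> (high-low)/4.  A Beta fit whose implied variance is
    infeasible (>= m(1-m)) falls back to a narrower SD with a logged warning.
    """
    m = spec.base
    if spec.family == "fixed" or spec.high <= spec.low:
        return Distribution(family="fixed", mean=m, sd=0.0)

    div = {"range95": 3.92, "range4": 4.0}[sd_rule]
    sd = (spec.high - spec.low) / div

    if spec.family == "beta":
        if not 0.0 < m < 1.0:
            # boundary mean: no non-degenerate beta has this mean
            return Distribution(family="fixed", mean=m, sd=0.0)
        vmax = m * (1.0 - m)
        if sd * sd >= vmax:
            sd_new = 0.5 * math.sqrt(vmax)
            logger.warning(
                "%s: range-implied SD %.4g infeasible for a Beta with mean %.4g; "
                "falling back to SD %.4g", spec.id, sd, m, sd_new,
            )
            sd = sd_new
        nu = vmax / (sd * sd) - 1.0
        return Distribution(family="beta", mean=m, sd=sd, a=m * nu, b=(1.0 - m) * nu)

    # gamma: shape k = m^2/v, scale theta = v/m
    v = sd * sd
    return Distribution(family="gamma", mean=m, sd=sd, a=m * m / v, b=v / m)


def distribution_mean(dist: Distribution) -> float:
    """Analytic mean of a fitted distribution (for validation)."""
    if dist.family == "fixed":
        return dist.mean
    if dist.family == "beta":
        return dist.a / (dist.a + dist.b)
    return dist.a * dist.b


def exact_binomial_ci(events: int, at_risk: int, level: float = 0.95):
    """Clopper-Pearson exact confidence interval for a binomial proportion."""
    if at_risk < 1:
        raise ValueError("at_risk must be >= 1")
    alpha = 1.0 - level
    lo = 0.0 if events == 0 else stats.beta.ppf(alpha / 2, events, at_risk - events + 1)
    hi = 1.0 if events == at_risk else stats.beta.ppf(
        1 - alpha / 2, events + 1, at_risk - events
    )
    return float(lo), float(hi)
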