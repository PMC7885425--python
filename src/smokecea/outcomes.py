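"""Outcome and cost valuation of a cohort trace.

Converts occupancy into discounted QALYs and discounted costs under either
costing perspective:

* **healthcare** — programme costs (charged once at cycle 0) plus annual
  treatment costs of the five smoking-related diseases (SRD), mixed over
  smoking statuses with the status-specific relative risks;
* **societal** — healthcare plus productivity losses from sick leave,
  valued by the human-capital approach (a day off work costs that day's
  wage).

Annual quantities (incidence, treatment costs, sick days) are halved per
6-month cycle. Utilities follow the lowest-utility comorbidity rule: a
person with several prevalent diseases takes the worst (largest) decrement.
Disease prevalences are treated as independent when computing the
comorbidity mix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import CohortTrace
from .parameters import (
    DiseaseParams,
    LabourParams,
    ParameterSet,
    ProgramCosts,
    UtilityParams,
    ValidationError,
)

__all__ = [
    "PerspectiveResult",
    "accumulate",
    "cycle_healthcare_cost",
    "cycle_utility",
    "discount_factor",
    "mixed_incidence",
    "mixed_prevalence",
    "productivity_loss",
]

_STATUSES = ("smoker", "former_smoker")


def mixed_incidence(inc_smoker: float, inc_former: float,
                    n_smoker: float, n_former: float) -> float:
    """Expected disease cases: incidence in each status times its headcount.

    Rates are status-specific annual incidences (background rate x relative
    risk); the result is in cases per year for the given occupancy.
    """
    for name, v in (("inc_smoker", inc_smoker), ("inc_former", inc_former),
                    ("n_smoker", n_smoker), ("n_former", n_former)):
        if v < 0:
            raise ValidationError(f"{name} must be >= 0, got {v!r}")
    return inc_former * n_former + inc_smoker * n_smoker


def mixed_prevalence(prev_smoker: float, prev_former: float,
                     w_smoker: float, w_former: float) -> float:
    """Population disease prevalence mixed over smoking statuses."""
    for name, v in (("prev_smoker", prev_smoker), ("prev_former", prev_former),
                    ("w_smoker", w_smoker), ("w_former", w_former)):
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"{name} must lie in [0, 1], got {v!r}")
    if w_smoker + w_former > 1.0 + 1e-12:
        raise ValidationError("status weights must sum to at most 1")
    return prev_smoker * w_smoker + prev_former * w_former


def discount_factor(rate: float, cycle_index: int) -> float:
    """Discount factor (1+rate)^(-t/2) for 6-month cycle ``t``."""
    if rate < 0:
        raise ValidationError("discount rate must be >= 0")
    return float((1.0 + rate) ** (-cycle_index * 0.5))


def _expected_utility(u_healthy: float, prev_dec: Sequence[tuple[float, float]]) -> float:
    """Expected utility of one person of a status, enumerating disease subsets.

    ``prev_dec`` holds (prevalence, decrement) per disease for this status.
    Diseases are independent; a person's utility is the healthy status
    utility minus the largest decrement among their prevalent diseases,
    clamped at 0.
    """
    n = len(prev_dec)
    total = 0.0
    clamped = False
    for mask in range(1 << n):
        p = 1.0
        worst = 0.0
        for i in range(n):
            prev, dec = prev_dec[i]
            if mask >> i & 1:
                p *= prev
                worst = max(worst, dec)
            else:
                p *= 1.0 - prev
        if p == 0.0:
            continue
        u = u_healthy - worst
        if u < 0:
            u, clamped = 0.0, True
        total += p * u
    if clamped:
        warnings.warn("utility decrement drove utility below 0; clamped to 0",
                      RuntimeWarning, stacklevel=3)
    return total


def cycle_utility(occupancy: Mapping[str, float], utilities: UtilityParams,
                  prevalence: Mapping[str, Sequence[tuple[float, float]]]) -> float:
    """QALYs accrued in one 6-month cycle.

    ``occupancy`` maps status ("smoker", "former_smoker") to alive persons;
    ``prevalence`` maps status to per-disease (prevalent fraction,
    utility decrement) pairs for that status.
    """
    qaly = 0.0
    for status, n in occupancy.items():
        if n < 0:
            raise ValidationError(f"occupancy[{status!r}] must be >= 0")
        if n == 0:
            continue
        u = _expected_utility(utilities.healthy(status), list(prevalence.get(status, ())))
        qaly += n * 0.5 * u
    return qaly


def cycle_healthcare_cost(incident_cases: Mapping[str, float],
                          prevalent_persons: Mapping[str, float],
                          diseases: Sequence[DiseaseParams],
                          program_costs: ProgramCosts,
                          cycle_index: int, arm: str,
                          cohort_size: float) -> float:
    """Direct healthcare cost of one cycle, in euros.

    The programme cost is charged once, at cycle 0, at the arm's per-patient
    rate times the cohort (plus the spread per-patient training rate for the
    combined arm). Disease treatment charges per cycle are half the annual
    rates: incident cases (cases/year) x incident cost x 0.5 plus prevalent
    persons x prevalent annual cost x 0.5.
    """
    by_name = {d.name: d for d in diseases}
    for name in set(incident_cases) | set(prevalent_persons):
        if name not in by_name:
            raise ValidationError(f"unknown disease {name!r}")
    cost = 0.0
    if cycle_index == 0:
        cost += program_costs.initial_cost(arm, cohort_size)
    for name, d in by_name.items():
        cost += incident_cases.get(name, 0.0) * d.cost_incident * 0.5
        cost += prevalent_persons.get(name, 0.0) * d.cost_prevalent * 0.5
    return cost


def productivity_loss(occupancy: Mapping[str, float], labour: LabourParams,
                      age: float, sex: str,
                      diseased_fraction: Mapping[str, float] | None = None) -> float:
    """Sick-leave productivity loss for one cycle (human-capital approach).

    Each person of a status loses ``sick_days[status]`` days/year, halved
    per cycle, valued at the daily wage times the sex/age-band employment
    fraction. When ``labour.restrict_to_diseased`` is set, only the
    SRD-prevalent fraction of each status (``diseased_fraction``) accrues
    the loss.
    """
    if age < 16:
        raise ValidationError(f"no employment data below age 16 (got {age})")
    emp = labour.employment_fraction(sex, age)
    wage = labour.daily_wage(sex)
    loss = 0.0
    for status, n in occupancy.items():
        if status not in labour.sick_days:
            raise ValidationError(f"unknown smoking status {status!r}")
        if labour.restrict_to_diseased:
            n = n * (diseased_fraction or {}).get(status, 0.0)
        loss += n * emp * labour.sick_days[status] * wage * 0.5
    return loss


@dataclass
class PerspectiveResult:
    """Totals of one cohort run under one costing perspective."""

    perspective: str
    arm: str
    sex: str
    cohort_size: float
    total_cost: float
    total_qalys: float
    total_productivity_loss: float
    ledger: pd.DataFrame

    @property
    def cost_per_person(self) -> float:
        return self.total_cost / self.cohort_size

    @property
    def qalys_per_person(self) -> float:
        return self.total_qalys / self.cohort_size


def accumulate(trace: CohortTrace, params: ParameterSet,
               perspective: str | None = None) -> PerspectiveResult:
    """Discounted totals for one trace under one perspective.

    Societal cost = healthcare cost + productivity losses; the healthcare
    perspective excludes productivity entirely. The per-cycle ledger
    (undiscounted and discounted streams) is attached for export.
    """
    if perspective is None:
        perspective = params.settings.perspective
    if perspective not in ("healthcare", "societal"):
        raise ValidationError(f"unknown perspective {perspective!r}")
    settings = params.settings
    rows = []
    occ = trace.occupancy
    ages = trace.ages
    for t in range(len(trace)):
        df_c = discount_factor(settings.discount_rate_costs, t)
        df_e = discount_factor(settings.discount_rate_effects, t)
        if t == 0:
            hc = cycle_healthcare_cost({}, {}, params.diseases, params.program_costs,
                                       0, trace.arm, trace.cohort_size)
            qaly = 0.0
            prod = 0.0
        else:
            n_s = occ[t, 0]
            n_f = occ[t, 1] + occ[t, 2]
            alive = n_s + n_f
            age = ages[t]
            incident: dict[str, float] = {}
            prevalent: dict[str, float] = {}
            prev_pairs: dict[str, list[tuple[float, float]]] = {s: [] for s in _STATUSES}
            for d in params.diseases:
                incident[d.name] = mixed_incidence(
                    d.incidence_for("smoker", age), d.incidence_for("former_smoker", age),
                    n_s, n_f)
                p_s = d.prevalence_for("smoker", age)
                p_f = d.prevalence_for("former_smoker", age)
                if alive > 0:
                    mix = mixed_prevalence(p_s, p_f, n_s / alive, n_f / alive)
                    prevalent[d.name] = mix * alive
                else:
                    prevalent[d.name] = 0.0
                prev_pairs["smoker"].append((p_s, d.utility_decrement))
                prev_pairs["former_smoker"].append((p_f, d.utility_decrement))
            hc = cycle_healthcare_cost(incident, prevalent, params.diseases,
                                       params.program_costs, t, trace.arm,
                                       trace.cohort_size)
            occupancy_by_status = {"smoker": n_s, "former_smoker": n_f}
            qaly = cycle_utility(occupancy_by_status, params.utilities, prev_pairs)
            if alive > 0:
                diseased = {
                    s: 1.0 - float(np.prod([1.0 - p for p, _ in prev_pairs[s]]))
                    for s in _STATUSES}
                prod = productivity_loss(occupancy_by_status, params.labour,
                                         age, settings.sex, diseased)
            else:
                prod = 0.0
        rows.append({
            "cycle": t,
            "qaly_undisc": qaly,
            "hc_cost_undisc": hc,
            "prod_loss_undisc": prod,
            "df_costs": df_c,
            "df_effects": df_e,
            "qaly_disc": qaly * df_e,
            "hc_cost_disc": hc * df_c,
            "prod_loss_disc": prod * df_c,
        })
    ledger = pd.DataFrame(rows)
    total_hc = float(ledger["hc_cost_disc"].sum())
    total_prod = float(ledger["prod_loss_disc"].sum())
    total_cost = total_hc + total_prod if perspective == "societal" else total_hc
    return PerspectiveResult(
        perspective=perspective,
        arm=trace.arm,
        sex=trace.sex,
        cohort_size=trace.cohort_size,
        total_cost=total_cost,
        total_qalys=float(ledger["qaly_disc"].sum()),
        total_productivity_loss=total_prod,
        ledger=ledger,
    )
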