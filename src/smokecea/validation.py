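"""Internal and external validation: life expectancy and life-years gained.

Validation runs the engine with behavioural transitions disabled (the
cohort stays in one smoking status), utility 1 and discount 0, so total
life-years / cohort size is a life expectancy. Model life expectancies can
then be compared with a reference life table, and the life-years gained
(LYG) from cessation at a given age is the difference between the
former-smoker and continuing-smoker life expectancies from that age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import run_cohort
from .parameters import (
    LifeTable,
    MortalitySchedule,
    ParameterSet,
    ValidationError,
    _mixture_life_expectancy,
)

__all__ = [
    "ValidationReport",
    "life_expectancy",
    "lyg_from_cessation",
    "validation_report",
]

_STATUS_PATHS = ("always_smoker", "quit_at_start", "never_transition")


def _frozen_params(params: ParameterSet, start_age: float, sex: str,
                   status_path: str) -> ParameterSet:
    """Copy of ``params`` with transitions disabled and the cohort pinned to
    one smoking status from ``start_age``."""
    if status_path not in _STATUS_PATHS:
        raise ValidationError(
            f"unknown status_path {status_path!r}; expected one of {_STATUS_PATHS}")
    p = params.copy()
    p.settings.sex = sex
    p.settings.start_age = float(start_age)
    p.settings.discount_rate_costs = 0.0
    p.settings.discount_rate_effects = 0.0
    for arm in p.transitions:
        tp = p.transitions[arm]
        tp.p_quit_first_cycle = 0.0
        tp.p_quit_later = 0.0
        tp.p_relapse_after_first_quit_cycle = 0.0
        tp.p_relapse_later = 0.0
    # Pin mortality to the chosen status: quit_at_start carries
    # former-smoker rates from the quit age on; the smoker paths carry
    # smoker rates throughout.
    sched = p.mortality
    q = (sched.q_cycle_former if status_path == "quit_at_start"
         else sched.q_cycle_smoker)
    p.mortality = MortalitySchedule(
        ages=sched.ages.copy(), q_cycle_smoker=q.copy(), q_cycle_former=q.copy(),
        calibration_factor=sched.calibration_factor, source=sched.source)
    return p


def life_expectancy(params: ParameterSet, start_age: float, sex: str,
                    status_path: str = "always_smoker",
                    max_age: float = 110.0) -> float:
    """Life expectancy in years at ``start_age`` for a fixed smoking status.

    ``quit_at_start`` applies former-smoker mortality from the quit age on;
    ``always_smoker`` (and its alias ``never_transition``) keeps smoker
    mortality throughout. Survivors of each 6-month cycle accrue 0.5 years.
    """
    if params.mortality.calibration_factor == 1.0 \
            and "calibrated" not in params.mortality.source:
        warnings.warn("mortality schedule is uncalibrated; proceeding with raw rates",
                      RuntimeWarning, stacklevel=2)
    p = _frozen_params(params, start_age, sex, status_path)
    trace = run_cohort(p, arm="advice", max_age=max_age)
    return trace.total_life_years / p.settings.cohort_size


def lyg_from_cessation(params: ParameterSet, quit_age: float, sex: str,
                       max_age: float = 110.0) -> float:
    """Life-years gained by quitting at ``quit_age`` vs. continuing to smoke
    (undiscounted, utility 1)."""
    le_quit = life_expectancy(params, quit_age, sex, "quit_at_start", max_age)
    le_smoke = life_expectancy(params, quit_age, sex, "always_smoker", max_age)
    return le_quit - le_smoke


@dataclass
class ValidationReport:
    """Model-vs-reference life expectancy and LYG-by-cessation-age tables."""

    life_expectancy_table: pd.DataFrame  # age, sex, model_le, reference_le, difference
    lyg_table: pd.DataFrame              # quit_age, sex, lyg
    gaps: list[str]

    def max_abs_difference(self) -> float:
        if self.life_expectancy_table.empty:
            return float("nan")
        return float(self.life_expectancy_table["difference"].abs().max())


def validation_report(params: ParameterSet,
                      reference: dict[str, LifeTable] | LifeTable,
                      ages: tuple[float, ...] = (16, 30, 50),
                      quit_ages: tuple[float, ...] = (40, 50, 60),
                      ) -> ValidationReport:
    """Compare modelled life expectancy against a reference life table.

    The model LE at each age uses the smoking-prevalence-weighted mixture
    of statuses implied by the parameter set (the same mixture the
    calibration targets); LYG rows come from :func:`lyg_from_cessation`.
    ``reference`` is one :class:`LifeTable` or a mapping sex -> table; ages
    missing from the reference are flagged, not fatal.
    """
    if isinstance(reference, LifeTable):
        reference = {reference.sex: reference}
    if not reference:
        raise ValidationError("empty reference life table")
    w = params.smoking_prevalence
    le_rows, lyg_rows, gaps = [], [], []
    for sex, table in reference.items():
        for age in ages:
            if age < table.ages.min() or age > table.ages.max():
                gaps.append(f"reference has no age {age} for {sex}")
                continue
            # Same objective the calibration targets: LE of the
            # prevalence-weighted mixture of status-specific rates.
            model_le = _mixture_life_expectancy(params.mortality, 1.0, w, age)
            ref_le = table.life_expectancy(age)
            le_rows.append({"age": age, "sex": sex, "model_le": model_le,
                            "reference_le": ref_le,
                            "difference": model_le - ref_le})
        for qa in quit_ages:
            lyg_rows.append({"quit_age": qa, "sex": sex,
                             "lyg": lyg_from_cessation(params, qa, sex)})
    return ValidationReport(
        life_expectancy_table=pd.DataFrame(le_rows),
        lyg_table=pd.DataFrame(lyg_rows),
        gaps=gaps,
    )
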