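"""Pairwise cost-utility comparison and deterministic sensitivity analysis.

The incremental cost-utility ratio (ICUR) is ΔCost/ΔQALY between the
combined programme (advice + text messaging) and health advice alone. A
strategy is *dominant* when it costs less and yields more QALYs, and
*dominated* in the opposite quadrant; a ratio is only meaningful for
trade-offs, though the signed ratio is also reported alongside a dominant
classification, as cost-utility tables conventionally print it.

Deterministic sensitivity analyses rerun the full pipeline over grids of
first-cycle quit probabilities (within their trial confidence intervals),
an older start age, equalized first-cycle relapse, and an alternative
discount rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .engine import first_cycle_quitters, run_cohort
from .outcomes import PerspectiveResult, accumulate
from .parameters import ParameterSet, ValidationError

__all__ = [
    "CEAResult",
    "SensitivityCell",
    "ShortTermSummary",
    "icur",
    "multivariate_sensitivity",
    "run_cea",
    "short_term_summary",
    "threshold_verdict",
    "univariate_sensitivity",
]

ARM_INTERVENTION = "combined"
ARM_COMPARATOR = "advice"


@dataclass
class CEAResult:
    """Incremental comparison of intervention vs. comparator."""

    delta_cost: float
    delta_qaly: float
    dominance: str  # dominant | dominated | tradeoff
    ratio: float | None  # ΔC/ΔQ, None when ΔQALY == 0
    perspective: str
    sex: str
    cohort_size: float

    @property
    def icur(self) -> float | None:
        """The ICUR; reported only for trade-offs (None otherwise)."""
        return self.ratio if self.dominance == "tradeoff" else None

    def rounded_ratio(self) -> float | None:
        """Reporting convention: nearest euro, one decimal below |100| €/QALY."""
        if self.ratio is None:
            return None
        if abs(self.ratio) < 100:
            return round(self.ratio, 1)
        return float(round(self.ratio))


def icur(intervention: PerspectiveResult, comparator: PerspectiveResult) -> CEAResult:
    """Incremental cost, incremental QALYs, ratio and dominance class."""
    if intervention.perspective != comparator.perspective:
        raise ValidationError("cannot compare results across perspectives")
    if intervention.sex != comparator.sex:
        raise ValidationError("cannot compare results across sexes")
    if not math.isclose(intervention.cohort_size, comparator.cohort_size):
        raise ValidationError("cannot compare results across cohort scales")
    d_cost = intervention.total_cost - comparator.total_cost
    d_qaly = intervention.total_qalys - comparator.total_qalys
    if d_cost < 0 and d_qaly > 0:
        dominance = "dominant"
    elif d_cost > 0 and d_qaly < 0:
        dominance = "dominated"
    else:
        dominance = "tradeoff"
    ratio = d_cost / d_qaly if d_qaly != 0 else None
    return CEAResult(delta_cost=d_cost, delta_qaly=d_qaly, dominance=dominance,
                     ratio=ratio, perspective=intervention.perspective,
                     sex=intervention.sex, cohort_size=intervention.cohort_size)


def threshold_verdict(result: CEAResult, threshold: float) -> str:
    """Classify against a willingness-to-pay threshold (€/QALY).

    Dominant results are labelled ``dominant`` regardless of the threshold;
    trade-offs are ``cost_effective`` when ICUR <= threshold.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    if result.dominance == "dominant":
        return "dominant"
    if result.dominance == "tradeoff" and result.ratio is not None \
            and result.ratio <= threshold:
        return "cost_effective"
    return "not_cost_effective"


def run_cea(params: ParameterSet, perspective: str | None = None,
            arm_intervention: str = ARM_INTERVENTION,
            arm_comparator: str = ARM_COMPARATOR) -> CEAResult:
    """Full pipeline: run both arms on one parameter set, value, compare."""
    res_i = accumulate(run_cohort(params, arm_intervention), params, perspective)
    res_c = accumulate(run_cohort(params, arm_comparator), params, perspective)
    return icur(res_i, res_c)


@dataclass
class ShortTermSummary:
    """Programme-end (6-month) comparison, before any disease costs accrue."""

    incremental_cost: float
    quitters_intervention: int
    quitters_comparator: int
    cost_per_additional_quitter: int


def short_term_summary(params: ParameterSet, n: float) -> ShortTermSummary:
    """Incremental 6-month cost and cost per additional quitter.

    The incremental cost is the per-patient programme cost difference times
    the cohort plus the (per-patient-spread) training cost of the combined
    arm; quitters are the expected first-cycle quitters per arm.
    """
    if n <= 0:
        raise ValidationError("cohort size must be > 0")
    pc = params.program_costs
    inc_cost = pc.initial_cost(ARM_INTERVENTION, n) - pc.initial_cost(ARM_COMPARATOR, n)
    q_i = first_cycle_quitters(params, ARM_INTERVENTION, n)
    q_c = first_cycle_quitters(params, ARM_COMPARATOR, n)
    if q_i == q_c:
        raise ValidationError(
            "equal quitters in both arms: cost per additional quitter undefined")
    per_quitter = int(math.floor(inc_cost / (q_i - q_c) + 0.5))
    return ShortTermSummary(incremental_cost=inc_cost, quitters_intervention=q_i,
                            quitters_comparator=q_c,
                            cost_per_additional_quitter=per_quitter)


@dataclass
class SensitivityCell:
    """One scenario of a deterministic sensitivity grid."""

    scenario: str
    axis: str
    value: float
    sex: str
    perspective: str
    result: CEAResult

    @property
    def icur_or_dominance(self) -> str:
        r = self.result.rounded_ratio()
        label = f"{r}" if r is not None else "undefined"
        if self.result.dominance == "dominant":
            label += " (DOMINANT)"
        return label


_AXES = ("p_quit_combined", "p_quit_advice", "start_age")


def _apply_axis(params: ParameterSet, axis: str, value: float) -> ParameterSet:
    p = params.copy()
    if axis == "p_quit_combined":
        p.transitions["combined"].p_quit_first_cycle = \
            _checked_prob(value, axis)
    elif axis == "p_quit_advice":
        p.transitions["advice"].p_quit_first_cycle = _checked_prob(value, axis)
    elif axis == "start_age":
        p.settings.start_age = float(value)
        if value < 16:
            raise ValidationError("start_age must be >= 16")
    else:
        raise ValidationError(f"unknown sensitivity axis {axis!r}; expected {_AXES}")
    return p


def _checked_prob(value: float, name: str) -> float:
    if not (0.0 <= value <= 1.0):
        raise ValidationError(f"{name} value {value!r} outside [0, 1]")
    return float(value)


def univariate_sensitivity(params_by_sex: dict[str, ParameterSet], axis: str,
                           values: Sequence[float],
                           perspectives: Iterable[str] = ("healthcare", "societal"),
                           ) -> list[SensitivityCell]:
    """One full model run per value x sex x perspective, all else at base."""
    if not values:
        raise ValidationError("sensitivity values must be nonempty")
    cells = []
    for value in values:
        for sex, base in params_by_sex.items():
            p = _apply_axis(base, axis, value)
            for persp in perspectives:
                cells.append(SensitivityCell(
                    scenario=f"{axis}={value}", axis=axis, value=float(value),
                    sex=sex, perspective=persp, result=run_cea(p, persp)))
    return cells


def multivariate_sensitivity(params_by_sex: dict[str, ParameterSet],
                             quit_grid_combined: Sequence[float],
                             quit_grid_advice: Sequence[float],
                             equalize_relapse: bool = True,
                             equalized_relapse_value: float = 0.5264,
                             perspectives: Iterable[str] = ("healthcare", "societal"),
                             ) -> list[SensitivityCell]:
    """Full cross of both arms' quit probabilities, with and (optionally)
    without the first-cycle relapse probabilities equalized."""
    if not quit_grid_combined or not quit_grid_advice:
        raise ValidationError("quit-probability grids must be nonempty")
    modes = [False, True] if equalize_relapse else [False]
    cells = []
    for equalized in modes:
        for q_cp in quit_grid_combined:
            for q_ha in quit_grid_advice:
                for sex, base in params_by_sex.items():
                    p = _apply_axis(base, "p_quit_combined", q_cp)
                    p = _apply_axis(p, "p_quit_advice", q_ha)
                    if equalized:
                        for arm in ("combined", "advice"):
                            p.transitions[arm].p_relapse_after_first_quit_cycle = \
                                _checked_prob(equalized_relapse_value, "relapse")
                    tag = "equalized_relapse" if equalized else "base_relapse"
                    for persp in perspectives:
                        cells.append(SensitivityCell(
                            scenario=f"cp={q_cp},ha={q_ha},{tag}",
                            axis="p_quit_combined*p_quit_advice",
                            value=float(q_cp), sex=sex, perspective=persp,
                            result=run_cea(p, persp)))
    return cells


def cells_to_frame(cells: Sequence[SensitivityCell]) -> pd.DataFrame:
    """Tidy table of a sensitivity grid (one row per scenario cell)."""
    return pd.DataFrame([{
        "scenario": c.scenario,
        "axis": c.axis,
        "value": c.value,
        "sex": c.sex,
        "perspective": c.perspective,
        "delta_cost": c.result.delta_cost,
        "delta_qaly": c.result.delta_qaly,
        "icur": c.result.rounded_ratio(),
        "dominance": c.result.dominance,
    } for c in cells])
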