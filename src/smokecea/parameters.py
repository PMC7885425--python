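"""Model inputs: types, validation, loading, and mortality calibration.

The central container is :class:`ParameterSet`, one fully validated input
bundle for a single sex and scenario, holding the transition probabilities
of both programme arms so the pair can be compared. Inputs come from the
packaged baseline (:func:`baseline_parameters`), optionally overridden by a
YAML/JSON config file (:func:`load_parameters`).

Status-specific mortality is calibrated to an all-cause reference life
table by a single multiplicative corrective factor per sex, found by scalar
root-finding so that the smoking-prevalence-weighted mixture reproduces the
reference life expectancy at the cohort start age
(:func:`calibrate_mortality`).
"""

from __future__ import annotations

import copy
import math
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from ._baseline import (
    ARMS,
    BASELINE,
    DISEASES,
    EMPLOYMENT_BANDS,
    SEXES,
    numeric_leaves,
    provenance_for,
)

__all__ = [
    "AgeSchedule",
    "CalibrationError",
    "DiseaseParams",
    "LabourParams",
    "LifeTable",
    "ModelSettings",
    "MortalitySchedule",
    "ParameterSet",
    "ProgramCosts",
    "TransitionParams",
    "UtilityParams",
    "ValidationError",
    "annual_to_cycle_probability",
    "baseline_parameters",
    "calibrate_mortality",
    "load_parameters",
]


class ValidationError(ValueError):
    """An input field violated its documented constraint."""


class CalibrationError(RuntimeError):
    """Mortality calibration could not bracket or reach the target."""


def _check_prob(name: str, value: float) -> float:
    if not (0.0 <= value <= 1.0):
        raise ValidationError(f"{name} must lie in [0, 1], got {value!r}")
    return float(value)


def _check_nonneg(name: str, value: float) -> float:
    if value < 0:
        raise ValidationError(f"{name} must be >= 0, got {value!r}")
    return float(value)


# ---------------------------------------------------------------------------
# age-band schedules


@dataclass(frozen=True)
class AgeSchedule:
    """Piecewise-constant schedule over age bands.

    ``breaks`` are ascending band lower bounds; band *i* covers ages in
    ``[breaks[i], breaks[i+1])`` and the last band is open-ended. Ages below
    the first break clamp to the first band (inputs given from age 16 are
    applied unchanged to any younger query, which the model never makes).
    """

    breaks: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.breaks) != len(self.values) or not self.breaks:
            raise ValidationError("AgeSchedule breaks/values must be equal-length, nonempty")
        if any(b2 <= b1 for b1, b2 in zip(self.breaks, self.breaks[1:])):
            raise ValidationError("AgeSchedule breaks must be strictly increasing")

    @classmethod
    def constant(cls, value: float) -> "AgeSchedule":
        return cls(breaks=(0.0,), values=(float(value),))

    def at(self, age: float) -> float:
        idx = bisect_right(self.breaks, age) - 1
        return self.values[max(idx, 0)]

    def to_dict(self) -> dict[str, list[float]]:
        return {"breaks": list(self.breaks), "values": list(self.values)}

    @classmethod
    def from_dict(cls, data: Mapping[str, Sequence[float]] | float) -> "AgeSchedule":
        if isinstance(data, (int, float)):
            return cls.constant(float(data))
        return cls(breaks=tuple(float(b) for b in data["breaks"]),
                   values=tuple(float(v) for v in data["values"]))


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ModelSettings:
    """Global analysis settings.

    The cycle length is fixed at half a year; ``horizon`` is ``"lifetime"``
    (run to ``max_age`` or cohort extinction) or an integer cycle cap.
    """

    cohort_size: float = 1000
    start_age: float = 45
    sex: str = "male"
    cycle_length: float = 0.5
    horizon: str | int = "lifetime"
    discount_rate_costs: float = 0.03
    discount_rate_effects: float = 0.03
    perspective: str = "healthcare"
    max_age: float = 100.0

    def __post_init__(self) -> None:
        if self.cohort_size <= 0:
            raise ValidationError("cohort_size must be > 0")
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.cycle_length != 0.5:
            raise ValidationError("cycle_length is fixed at 0.5 years")
        if self.start_age < 16:
            raise ValidationError("start_age must be >= 16")
        for name in ("discount_rate_costs", "discount_rate_effects"):
            _check_prob(name, getattr(self, name))
        if self.perspective not in ("healthcare", "societal"):
            raise ValidationError("perspective must be 'healthcare' or 'societal'")
        if isinstance(self.horizon, int) and self.horizon < 1:
            raise ValidationError("integer horizon must be >= 1 cycle")


@dataclass
class TransitionParams:
    """Behavioural per-cycle transition probabilities for one arm."""

    p_quit_first_cycle: float
    p_quit_later: float
    p_relapse_after_first_quit_cycle: float
    p_relapse_later: float
    max_quit_attempts_per_year: int = 2

    def __post_init__(self) -> None:
        for name in ("p_quit_first_cycle", "p_quit_later",
                     "p_relapse_after_first_quit_cycle", "p_relapse_later"):
            _check_prob(name, getattr(self, name))
        if self.max_quit_attempts_per_year < 1:
            raise ValidationError("max_quit_attempts_per_year must be >= 1")


@dataclass
class MortalitySchedule:
    """Per-cycle death probability by age for smokers and former smokers.

    Ages are integer years; a query at fractional age floors to the covered
    integer age and clamps to the table's range. ``calibration_factor`` is
    the corrective factor last applied (1.0 for raw schedules); it is always
    applied identically to both smoking statuses.
    """

    ages: np.ndarray
    q_cycle_smoker: np.ndarray
    q_cycle_former: np.ndarray
    calibration_factor: float = 1.0
    source: str = "unspecified"

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.q_cycle_smoker = np.asarray(self.q_cycle_smoker, dtype=float)
        self.q_cycle_former = np.asarray(self.q_cycle_former, dtype=float)
        if not (len(self.ages) == len(self.q_cycle_smoker) == len(self.q_cycle_former)):
            raise ValidationError("mortality arrays must be equal length")
        for name, arr in (("q_cycle_smoker", self.q_cycle_smoker),
                          ("q_cycle_former", self.q_cycle_former)):
            if np.any((arr < 0) | (arr > 1)):
                raise ValidationError(f"{name} probabilities must lie in [0, 1]")
        if self.calibration_factor <= 0:
            raise ValidationError("calibration_factor must be positive")

    @classmethod
    def from_annual(cls, ages: Sequence[float], q_annual_smoker: Sequence[float],
                    q_annual_former: Sequence[float], *, convention: str = "exact",
                    source: str = "unspecified") -> "MortalitySchedule":
        """Build from annual death probabilities.

        ``convention="exact"`` uses q_cycle = 1 - (1-q)^0.5 (constant hazard
        within the year); ``"half"`` uses q/2.
        """
        qs = np.asarray(q_annual_smoker, dtype=float)
        qf = np.asarray(q_annual_former, dtype=float)
        return cls(ages=np.asarray(ages, dtype=float),
                   q_cycle_smoker=annual_to_cycle_probability(qs, mode=convention),
                   q_cycle_former=annual_to_cycle_probability(qf, mode=convention),
                   source=source)

    def _index(self, age: float) -> int:
        idx = int(np.searchsorted(self.ages, math.floor(age), side="right")) - 1
        if idx < 0:
            raise ValidationError(
                f"no mortality entry at or below age {age} (table starts at {self.ages[0]})")
        return min(idx, len(self.ages) - 1)

    def q_cycle(self, status: str, age: float) -> float:
        """Per-cycle death probability for ``status`` at ``age``."""
        idx = self._index(age)
        if status == "smoker":
            return float(self.q_cycle_smoker[idx])
        if status in ("former_smoker", "former"):
            return float(self.q_cycle_former[idx])
        raise ValidationError(f"unknown smoking status {status!r}")

    def scaled(self, factor: float) -> "MortalitySchedule":
        """Return a copy with both statuses' probabilities scaled by ``factor``
        (clamped at 1)."""
        return MortalitySchedule(
            ages=self.ages.copy(),
            q_cycle_smoker=np.minimum(self.q_cycle_smoker * factor, 1.0),
            q_cycle_former=np.minimum(self.q_cycle_former * factor, 1.0),
            calibration_factor=self.calibration_factor * factor,
            source=self.source,
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "ages": [float(a) for a in self.ages],
            "q_cycle_smoker": [float(q) for q in self.q_cycle_smoker],
            "q_cycle_former": [float(q) for q in self.q_cycle_former],
            "calibration_factor": float(self.calibration_factor),
            "source": self.source,
        }


@dataclass
class DiseaseParams:
    """One smoking-related disease: background epidemiology, excess risks,
    unit costs (2018 euros per year), and utility decrement.

    ``incidence``/``prevalence`` are background (non-smoker-proxy) annual
    schedules by age; status-specific rates are background x relative risk.
    """

    name: str
    incidence: AgeSchedule
    prevalence: AgeSchedule
    rr_smoker: float
    rr_former: float
    cost_incident: float
    cost_prevalent: float
    utility_decrement: float
    sick_leave_linked: bool = True

    def __post_init__(self) -> None:
        if not (self.rr_smoker >= self.rr_former >= 1.0):
            raise ValidationError(
                f"{self.name}: require rr_smoker >= rr_former >= 1 "
                f"(got {self.rr_smoker}, {self.rr_former})")
        _check_nonneg(f"{self.name}.cost_incident", self.cost_incident)
        _check_nonneg(f"{self.name}.cost_prevalent", self.cost_prevalent)
        _check_prob(f"{self.name}.utility_decrement", self.utility_decrement)
        for sched, what in ((self.incidence, "incidence"), (self.prevalence, "prevalence")):
            if any(v < 0 for v in sched.values):
                raise ValidationError(f"{self.name}.{what} values must be >= 0")

    def prevalence_for(self, status: str, age: float) -> float:
        rr = self.rr_smoker if status == "smoker" else self.rr_former
        return min(self.prevalence.at(age) * rr, 1.0)

    def incidence_for(self, status: str, age: float) -> float:
        rr = self.rr_smoker if status == "smoker" else self.rr_former
        return self.incidence.at(age) * rr


@dataclass
class UtilityParams:
    u_smoker_healthy: float = 0.75
    u_former_healthy: float = 0.78
    comorbidity_rule: str = "lowest_utility"

    def __post_init__(self) -> None:
        _check_prob("u_smoker_healthy", self.u_smoker_healthy)
        _check_prob("u_former_healthy", self.u_former_healthy)
        if self.u_former_healthy < self.u_smoker_healthy:
            raise ValidationError("u_former_healthy must be >= u_smoker_healthy")
        if self.comorbidity_rule != "lowest_utility":
            raise ValidationError("only the 'lowest_utility' comorbidity rule is supported")

    def healthy(self, status: str) -> float:
        return self.u_smoker_healthy if status == "smoker" else self.u_former_healthy


@dataclass
class ProgramCosts:
    """Per-patient programme costs per arm, 2018 euros.

    The per-patient totals are authoritative; the itemized components are
    informative only (they do not sum to the totals in the source tables).
    One-off per-group items (training, combined arm) are spread over
    ``reference_group_size`` patients to give a per-patient rate, so costs
    scale linearly in cohort size.
    """

    per_patient: dict[str, float]
    items: dict[str, float] = field(default_factory=dict)
    training_combined_total: float = 1900.0
    reference_group_size: int = 1000

    def __post_init__(self) -> None:
        for arm in ARMS:
            if arm not in self.per_patient:
                raise ValidationError(f"per_patient cost missing for arm {arm!r}")
            _check_nonneg(f"per_patient.{arm}", self.per_patient[arm])
        _check_nonneg("training_combined_total", self.training_combined_total)
        if self.reference_group_size <= 0:
            raise ValidationError("reference_group_size must be > 0")

    @property
    def training_per_patient(self) -> float:
        return self.training_combined_total / self.reference_group_size

    def initial_cost(self, arm: str, cohort_size: float) -> float:
        """Total programme cost charged at cycle 0 for a cohort."""
        if arm not in ARMS:
            raise ValidationError(f"unknown arm {arm!r}")
        total = self.per_patient[arm] * cohort_size
        if arm == "combined":
            total += self.training_per_patient * cohort_size
        return total


@dataclass
class LabourParams:
    """Labour-market inputs for human-capital productivity costing."""

    employment: dict[str, dict[str, float]]
    hourly_wage: dict[str, float]
    monthly_agreed_hours: float = 155.0
    sick_days: dict[str, float] = field(
        default_factory=lambda: {"smoker": 11.0, "former_smoker": 7.0})
    days_per_year: float = 365.0
    restrict_to_diseased: bool = False

    def __post_init__(self) -> None:
        for sex in SEXES:
            if sex not in self.employment or sex not in self.hourly_wage:
                raise ValidationError(f"labour inputs missing for sex {sex!r}")
            for band in EMPLOYMENT_BANDS:
                _check_prob(f"employment.{sex}.{band}", self.employment[sex][band])
            _check_nonneg(f"hourly_wage.{sex}", self.hourly_wage[sex])
        _check_nonneg("monthly_agreed_hours", self.monthly_agreed_hours)
        for status in ("smoker", "former_smoker"):
            _check_nonneg(f"sick_days.{status}", self.sick_days[status])
        if self.sick_days["smoker"] < self.sick_days["former_smoker"]:
            raise ValidationError("smoker sick days must be >= former-smoker sick days")
        if self.days_per_year <= 0:
            raise ValidationError("days_per_year must be > 0")

    @staticmethod
    def band_for(age: float) -> str:
        if age < 16:
            raise ValidationError(f"no employment band below age 16 (got {age})")
        if age < 25:
            return "16-24"
        if age < 35:
            return "25-34"
        if age < 45:
            return "35-44"
        if age < 55:
            return "45-54"
        return "55+"

    def employment_fraction(self, sex: str, age: float) -> float:
        return self.employment[sex][self.band_for(age)]

    def daily_wage(self, sex: str) -> float:
        return self.hourly_wage[sex] * self.monthly_agreed_hours * 12.0 / self.days_per_year


@dataclass
class ParameterSet:
    """Complete, validated input bundle for one sex and scenario."""

    settings: ModelSettings
    transitions: dict[str, TransitionParams]
    mortality: MortalitySchedule
    diseases: list[DiseaseParams]
    utilities: UtilityParams
    program_costs: ProgramCosts
    labour: LabourParams
    threshold: float = 22000.0
    smoking_prevalence: float = 0.34
    arm: str = "combined"

    def __post_init__(self) -> None:
        for arm in ARMS:
            if arm not in self.transitions:
                raise ValidationError(f"transitions missing for arm {arm!r}")
        if self.arm not in ARMS:
            raise ValidationError(f"unknown arm {self.arm!r}")
        if self.threshold <= 0:
            raise ValidationError("threshold must be > 0")
        _check_prob("smoking_prevalence", self.smoking_prevalence)
        names = [d.name for d in self.diseases]
        if len(names) != len(set(names)):
            raise ValidationError("disease names must be unique")

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def disease(self, name: str) -> DiseaseParams:
        for d in self.diseases:
            if d.name == name:
                return d
        raise ValidationError(f"unknown disease {name!r}")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "settings": {k: getattr(self.settings, k) for k in (
                "cohort_size", "start_age", "sex", "cycle_length", "horizon",
                "discount_rate_costs", "discount_rate_effects", "perspective",
                "max_age")},
            "arm": self.arm,
            "threshold": self.threshold,
            "calibration": {"smoking_prevalence": self.smoking_prevalence},
            "transitions": {
                arm: {k: getattr(tp, k) for k in (
                    "p_quit_first_cycle", "p_quit_later",
                    "p_relapse_after_first_quit_cycle", "p_relapse_later",
                    "max_quit_attempts_per_year")}
                for arm, tp in self.transitions.items()},
            "mortality": self.mortality.to_dict(),
            "utilities": {k: getattr(self.utilities, k) for k in (
                "u_smoker_healthy", "u_former_healthy", "comorbidity_rule")},
            "program_costs": {
                "per_patient": dict(self.program_costs.per_patient),
                "items": dict(self.program_costs.items),
                "training_combined_total": self.program_costs.training_combined_total,
                "reference_group_size": self.program_costs.reference_group_size,
            },
            "labour": {
                "employment": {s: dict(b) for s, b in self.labour.employment.items()},
                "hourly_wage": dict(self.labour.hourly_wage),
                "monthly_agreed_hours": self.labour.monthly_agreed_hours,
                "sick_days": dict(self.labour.sick_days),
                "days_per_year": self.labour.days_per_year,
                "restrict_to_diseased": self.labour.restrict_to_diseased,
            },
            "diseases": {
                d.name: {
                    "rr_smoker": d.rr_smoker,
                    "rr_former": d.rr_former,
                    "cost_incident": d.cost_incident,
                    "cost_prevalent": d.cost_prevalent,
                    "utility_decrement": d.utility_decrement,
                    "sick_leave_linked": d.sick_leave_linked,
                    "incidence": d.incidence.to_dict(),
                    "prevalence": d.prevalence.to_dict(),
                }
                for d in self.diseases},
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ParameterSet":
        return _build_parameter_set(dict(data))


# ---------------------------------------------------------------------------
# probability conversion


def annual_to_cycle_probability(p_annual, *, mode: str = "half"):
    """Convert an annual probability to a 6-month-cycle probability.

    ``mode="half"`` divides by two — the convention the behavioural inputs
    imply (a 10 %/year relapse rate is used as 0.05 per cycle).
    ``mode="exact"`` uses the constant-hazard form 1 - (1-p)^0.5, the usual
    rate conversion for mortality. Accepts scalars or arrays.
    """
    arr = np.asarray(p_annual, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValidationError("annual probability must lie in [0, 1]")
    if mode == "half":
        out = arr / 2.0
    elif mode == "exact":
        out = 1.0 - np.power(1.0 - arr, 0.5)
    else:
        raise ValidationError(f"unknown conversion mode {mode!r}")
    return float(out) if np.isscalar(p_annual) or arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# life tables and calibration


@dataclass
class LifeTable:
    """All-cause annual death probabilities by integer age for one sex."""

    ages: np.ndarray
    qx: np.ndarray
    sex: str = "male"

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.qx = np.asarray(self.qx, dtype=float)
        if len(self.ages) != len(self.qx):
            raise ValidationError("life table ages/qx must be equal length")
        if np.any((self.qx < 0) | (self.qx > 1)):
            raise ValidationError("life table qx must lie in [0, 1]")

    @classmethod
    def read_csv(cls, path: str | Path, sex: str) -> "LifeTable":
        """Read a CSV with columns ``age, sex, qx`` (annual probability)."""
        df = pd.read_csv(path)
        missing = {"age", "sex", "qx"} - set(df.columns)
        if missing:
            raise ValidationError(f"life table CSV missing columns: {sorted(missing)}")
        sub = df[df["sex"] == sex].sort_values("age")
        if sub.empty:
            raise ValidationError(f"life table CSV has no rows for sex {sex!r}")
        return cls(ages=sub["age"].to_numpy(), qx=sub["qx"].to_numpy(), sex=sex)

    def q_cycle_array(self) -> np.ndarray:
        return annual_to_cycle_probability(self.qx, mode="exact")

    def life_expectancy(self, start_age: float, max_age: float = 110.0) -> float:
        return _ladder_life_expectancy(self.ages, self.q_cycle_array(), start_age, max_age)


def _ladder_life_expectancy(ages: np.ndarray, q_cycle: np.ndarray,
                            start_age: float, max_age: float = 110.0) -> float:
    """Half-year survival ladder; life-years accrue after each transition
    (survivors of cycle t contribute 0.5 years), matching the engine's
    cycle-counting convention."""
    le = 0.0
    surv = 1.0
    age = float(start_age)
    while age < max_age and surv > 1e-12:
        idx = int(np.searchsorted(ages, math.floor(age), side="right")) - 1
        idx = min(max(idx, 0), len(ages) - 1)
        surv *= 1.0 - q_cycle[idx]
        le += surv * 0.5
        age += 0.5
    return le


def _mixture_life_expectancy(schedule: MortalitySchedule, factor: float,
                             w_smoker: float, start_age: float,
                             max_age: float = 110.0) -> float:
    q_mix = np.minimum(
        factor * (w_smoker * schedule.q_cycle_smoker
                  + (1.0 - w_smoker) * schedule.q_cycle_former), 1.0)
    return _ladder_life_expectancy(schedule.ages, q_mix, start_age, max_age)


def calibrate_mortality(reference: MortalitySchedule,
                        target: "LifeTable | float",
                        smoking_prevalence: float,
                        *, start_age: float = 16.0,
                        tolerance_years: float = 0.1,
                        bracket: tuple[float, float] = (0.1, 10.0),
                        max_age: float = 110.0) -> MortalitySchedule:
    """Find the corrective factor matching the mixture to a target life table.

    A single positive scalar ``f`` is applied identically to smoker and
    former-smoker per-cycle probabilities so that the life expectancy at
    ``start_age`` of the smoking-prevalence-weighted mixture equals the
    target's (life table, or a life expectancy in years given directly).

    Raises :class:`CalibrationError` when no root lies in ``bracket`` or the
    bracketed root misses the target by more than ``tolerance_years``.
    """
    w = _check_prob("smoking_prevalence", smoking_prevalence)
    if isinstance(target, LifeTable):
        target_le = target.life_expectancy(start_age, max_age)
    else:
        target_le = float(target)
    if target_le <= 0:
        raise CalibrationError(f"target life expectancy must be positive, got {target_le}")

    def gap(f: float) -> float:
        return _mixture_life_expectancy(reference, f, w, start_age, max_age) - target_le

    lo, hi = bracket
    g_lo, g_hi = gap(lo), gap(hi)
    # LE decreases in f, so gap(lo) should be >= 0 >= gap(hi).
    if g_lo * g_hi > 0:
        raise CalibrationError(
            "no corrective factor in bracket "
            f"[{lo}, {hi}]: LE gap at bounds = ({g_lo:+.3f}, {g_hi:+.3f}) years "
            f"for target LE {target_le:.3f} at age {start_age}")
    f_star = float(brentq(gap, lo, hi, xtol=1e-12, rtol=1e-12))
    residual = gap(f_star)
    if abs(residual) > tolerance_years:
        raise CalibrationError(
            f"calibration residual {residual:+.3f} years exceeds tolerance "
            f"{tolerance_years}; per-cycle probabilities may be saturating at 1")
    out = reference.scaled(f_star)
    # scaled() compounds factors; record this calibration's own factor too.
    out.source = f"{reference.source} (calibrated f={f_star:.6g})"
    return out


# ---------------------------------------------------------------------------
# loading / building


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def _resolve_sexed(value: Any, sex: str) -> float:
    if isinstance(value, Mapping):
        return float(value[sex])
    return float(value)


def _build_mortality(cfg: dict[str, Any], sex: str) -> MortalitySchedule:
    mcfg = cfg.get("mortality", {"source": "synthetic-default"})
    if "q_cycle_smoker" in mcfg:
        return MortalitySchedule(
            ages=np.asarray(mcfg["ages"], dtype=float),
            q_cycle_smoker=np.asarray(mcfg["q_cycle_smoker"], dtype=float),
            q_cycle_former=np.asarray(mcfg["q_cycle_former"], dtype=float),
            calibration_factor=float(mcfg.get("calibration_factor", 1.0)),
            source=str(mcfg.get("source", "config")),
        )
    if "csv" in mcfg:
        df = pd.read_csv(mcfg["csv"])
        sub = df[df["sex"] == sex].sort_values("age")
        if sub.empty:
            raise ValidationError(f"mortality CSV has no rows for sex {sex!r}")
        return MortalitySchedule.from_annual(
            sub["age"].to_numpy(), sub["q_smoker"].to_numpy(),
            sub["q_former"].to_numpy(), source=str(mcfg["csv"]))
    if mcfg.get("source") == "synthetic-default":
        from .fixtures import SyntheticSpec, synthetic_life_table
        spec = SyntheticSpec.from_dict(cfg["synthetic"])
        return synthetic_life_table(spec, sex=sex)
    raise ValidationError("mortality config must give arrays, a csv path, or synthetic-default")


def _build_diseases(cfg: dict[str, Any], sex: str) -> list[DiseaseParams]:
    from .fixtures import SyntheticSpec, synthetic_age_schedules
    spec = SyntheticSpec.from_dict(cfg["synthetic"])
    synth = synthetic_age_schedules(spec, sex=sex)
    out = []
    for name, dcfg in cfg["diseases"].items():
        incidence = (AgeSchedule.from_dict(dcfg["incidence"])
                     if "incidence" in dcfg else synth[name]["incidence"])
        prevalence = (AgeSchedule.from_dict(dcfg["prevalence"])
                      if "prevalence" in dcfg else synth[name]["prevalence"])
        out.append(DiseaseParams(
            name=name,
            incidence=incidence,
            prevalence=prevalence,
            rr_smoker=_resolve_sexed(dcfg["rr_smoker"], sex),
            rr_former=_resolve_sexed(dcfg["rr_former"], sex),
            cost_incident=float(dcfg["cost_incident"]),
            cost_prevalent=float(dcfg["cost_prevalent"]),
            utility_decrement=float(dcfg["utility_decrement"]),
            sick_leave_linked=bool(dcfg.get("sick_leave_linked", True)),
        ))
    return out


def _build_parameter_set(cfg: dict[str, Any]) -> ParameterSet:
    cfg = _deep_merge(BASELINE, cfg)
    scfg = cfg["settings"]
    settings = ModelSettings(**scfg)
    sex = settings.sex
    transitions = {arm: TransitionParams(**cfg["transitions"][arm]) for arm in ARMS}
    lcfg = cfg["labour"]
    labour = LabourParams(
        employment={s: dict(lcfg["employment"][s]) for s in SEXES},
        hourly_wage={s: float(lcfg["hourly_wage"][s]) for s in SEXES},
        monthly_agreed_hours=float(lcfg["monthly_agreed_hours"]),
        sick_days=dict(lcfg["sick_days"]),
        days_per_year=float(lcfg.get("days_per_year", 365.0)),
        restrict_to_diseased=bool(lcfg.get("restrict_to_diseased", False)),
    )
    pcfg = cfg["program_costs"]
    program_costs = ProgramCosts(
        per_patient=dict(pcfg["per_patient"]),
        items=dict(pcfg.get("items", {})),
        training_combined_total=float(pcfg["training_combined_total"]),
        reference_group_size=int(pcfg["reference_group_size"]),
    )
    return ParameterSet(
        settings=settings,
        transitions=transitions,
        mortality=_build_mortality(cfg, sex),
        diseases=_build_diseases(cfg, sex),
        utilities=UtilityParams(**cfg["utilities"]),
        program_costs=program_costs,
        labour=labour,
        threshold=float(cfg["threshold"]),
        smoking_prevalence=float(cfg["calibration"]["smoking_prevalence"]),
        arm=str(cfg.get("arm", "combined")),
    )


def baseline_parameters(arm: str = "combined", sex: str = "male") -> ParameterSet:
    """The packaged baseline :class:`ParameterSet` for one arm and sex.

    Transition probabilities for *both* arms are included (a cost-utility
    comparison needs the pair); ``arm`` selects the active intervention arm
    recorded on the set.
    """
    if arm not in ARMS:
        raise ValidationError(f"unknown arm {arm!r}; expected one of {ARMS}")
    if sex not in SEXES:
        raise ValidationError(f"unknown sex {sex!r}; expected one of {SEXES}")
    return _build_parameter_set({"settings": {"sex": sex}, "arm": arm})


def load_parameters(config_path: str | Path) -> ParameterSet:
    """Load a YAML/JSON config, fill gaps from the packaged baseline, validate.

    The schema mirrors :meth:`ParameterSet.to_dict`; any subset of keys may
    be given and missing fields fall back to the baseline.
    """
    path = Path(config_path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text())
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValidationError("config root must be a mapping")
    return _build_parameter_set(data)


def baseline_provenance() -> dict[str, str]:
    """Provenance tag for every numeric field of the packaged baseline."""
    return {path: provenance_for(path) for path, _ in numeric_leaves(BASELINE)}
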