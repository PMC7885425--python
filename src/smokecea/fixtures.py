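"""Synthetic inputs: life tables, disease schedules, and toy scenarios.

Nothing here mimics any real national statistics quantitatively; the
generators reproduce the *statistical structure* the analysis assumes —
smoothly age-increasing (Gompertz) mortality, a smoker hazard excess over
former smokers, age-increasing disease incidence and prevalence, and
ordered relative risks — so every stage of the pipeline is testable with
no external data. All generators are pure functions of a
:class:`SyntheticSpec` (deterministic given its seed).

:func:`toy_scenario` additionally ships a 3-cycle, constant-mortality,
one-disease scenario together with expected results computed by an
independent spreadsheet-style oracle (explicit scalar arithmetic, no
engine code), for end-to-end equality tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

from ._baseline import BASELINE, DISEASES
from .parameters import (
    AgeSchedule,
    DiseaseParams,
    MortalitySchedule,
    ParameterSet,
    ValidationError,
    baseline_parameters,
)

__all__ = [
    "SyntheticSpec",
    "synthetic_age_schedules",
    "synthetic_disease_set",
    "synthetic_life_table",
    "toy_scenario",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic-input generators (see package baseline
    for the shipped defaults and their meaning)."""

    seed: int = 20180101
    gompertz: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: BASELINE["synthetic"]["gompertz"])
    smoker_hazard_ratio: float = 1.8
    incidence_at_40: Mapping[str, float] = field(
        default_factory=lambda: BASELINE["synthetic"]["incidence_at_40"])
    incidence_growth: float = 0.06
    prevalence_at_40: Mapping[str, float] = field(
        default_factory=lambda: BASELINE["synthetic"]["prevalence_at_40"])
    prevalence_growth: float = 0.04
    prevalence_cap: float = 0.60
    female_rate_ratio: float = 0.7
    age_min: int = 16
    age_max: int = 110
    band_width: int = 5
    noise_level: float = 0.0

    def __post_init__(self) -> None:
        for sex, pars in self.gompertz.items():
            if pars["intercept"] <= 0 or pars["slope"] <= 0:
                raise ValidationError(f"Gompertz parameters for {sex} must be positive")
        if self.smoker_hazard_ratio < 1.0:
            raise ValidationError("smoker_hazard_ratio must be >= 1")
        if self.noise_level < 0:
            raise ValidationError("noise_level must be >= 0")
        if self.age_min >= self.age_max:
            raise ValidationError("age_min must be below age_max")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "SyntheticSpec":
        return cls(**{k: v for k, v in data.items()})

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed + salt) % 2**31)


def synthetic_life_table(spec: SyntheticSpec, sex: str = "male") -> MortalitySchedule:
    """Per-cycle mortality by age and smoking status from a Gompertz hazard.

    Former-smoker annual hazard h(a) = intercept * exp(slope * a); smoker
    hazard is that times the smoker hazard ratio. Optional multiplicative
    log-normal noise (sd ``noise_level``) perturbs ages independently but
    preserves the smoker/former ratio; with the default noise 0 the table
    is strictly increasing in age.
    """
    ages = np.arange(spec.age_min, spec.age_max + 1, dtype=float)
    pars = spec.gompertz[sex]
    hazard_former = pars["intercept"] * np.exp(pars["slope"] * ages)
    if spec.noise_level > 0:
        rng = spec.rng(salt={"male": 1, "female": 2}.get(sex, 3))
        hazard_former = hazard_former * np.exp(
            rng.normal(0.0, spec.noise_level, size=ages.shape))
    hazard_smoker = hazard_former * spec.smoker_hazard_ratio
    q_former = 1.0 - np.exp(-hazard_former)
    q_smoker = 1.0 - np.exp(-hazard_smoker)
    return MortalitySchedule.from_annual(
        ages, q_smoker, q_former, convention="exact",
        source=f"synthetic-gompertz-{sex}-seed{spec.seed}")


def synthetic_age_schedules(spec: SyntheticSpec, sex: str = "male",
                            ) -> dict[str, dict[str, AgeSchedule]]:
    """Deterministic age-banded incidence/prevalence schedules per disease.

    Exponential growth with age, piecewise-constant over ``band_width``-year
    bands, evaluated at each band's lower bound; female rates are the male
    rates times ``female_rate_ratio``.
    """
    breaks = tuple(float(a) for a in
                   range(spec.age_min, spec.age_max + 1, spec.band_width))
    sex_ratio = 1.0 if sex == "male" else spec.female_rate_ratio
    out: dict[str, dict[str, AgeSchedule]] = {}
    for name in DISEASES:
        inc0 = spec.incidence_at_40[name] * sex_ratio
        prev0 = spec.prevalence_at_40[name] * sex_ratio
        inc_vals = tuple(inc0 * math.exp(spec.incidence_growth * (b - 40.0))
                         for b in breaks)
        prev_vals = tuple(min(prev0 * math.exp(spec.prevalence_growth * (b - 40.0)),
                              spec.prevalence_cap)
                          for b in breaks)
        out[name] = {"incidence": AgeSchedule(breaks, inc_vals),
                     "prevalence": AgeSchedule(breaks, prev_vals)}
    return out


def synthetic_disease_set(spec: SyntheticSpec, sex: str = "male") -> list[DiseaseParams]:
    """Five fully synthetic diseases with randomized but ordered relative
    risks and costs, for property testing (the packaged baseline instead
    combines published RRs/costs with synthetic schedules)."""
    rng = spec.rng(salt=7)
    schedules = synthetic_age_schedules(spec, sex)
    out = []
    for name in DISEASES:
        rr_former = 1.0 + rng.uniform(0.2, 2.0)
        rr_smoker = rr_former + rng.uniform(0.1, 6.0)
        out.append(DiseaseParams(
            name=name,
            incidence=schedules[name]["incidence"],
            prevalence=schedules[name]["prevalence"],
            rr_smoker=rr_smoker,
            rr_former=rr_former,
            cost_incident=float(rng.uniform(1000, 15000)),
            cost_prevalent=float(rng.uniform(500, 8000)),
            utility_decrement=float(rng.uniform(0.05, 0.3)),
        ))
    return out


# ---------------------------------------------------------------------------
# toy scenario with an independent oracle


_TOY_Q = 0.02          # per-cycle death probability, both statuses, all ages
_TOY_CYCLES = 3
_TOY_PREV = 0.10       # background prevalence of the single toy disease
_TOY_INC = 0.01        # background annual incidence
_TOY_RR_S, _TOY_RR_F = 2.0, 1.5
_TOY_DEC = 0.10
_TOY_COST_INC, _TOY_COST_PREV = 5000.0, 1000.0


def _toy_params(sex: str = "male") -> ParameterSet:
    p = baseline_parameters("combined", sex)
    p.settings.cohort_size = 100
    p.settings.start_age = 45
    p.settings.horizon = _TOY_CYCLES
    ages = np.arange(16.0, 111.0)
    p.mortality = MortalitySchedule(
        ages=ages,
        q_cycle_smoker=np.full_like(ages, _TOY_Q),
        q_cycle_former=np.full_like(ages, _TOY_Q),
        source="synthetic-toy-constant")
    p.diseases = [DiseaseParams(
        name="toy_disease",
        incidence=AgeSchedule.constant(_TOY_INC),
        prevalence=AgeSchedule.constant(_TOY_PREV),
        rr_smoker=_TOY_RR_S, rr_former=_TOY_RR_F,
        cost_incident=_TOY_COST_INC, cost_prevalent=_TOY_COST_PREV,
        utility_decrement=_TOY_DEC)]
    return p


def _toy_oracle(p: ParameterSet, arm: str, perspective: str) -> dict[str, float]:
    """Spreadsheet-style expected results for the toy scenario.

    Explicit scalar bookkeeping, independent of the engine/outcomes code
    paths: state occupancies are advanced cell by cell exactly as one would
    in a spreadsheet.
    """
    tp = p.transitions[arm]
    n0 = p.settings.cohort_size
    r_c = p.settings.discount_rate_costs
    r_e = p.settings.discount_rate_effects
    u_s, u_f = p.utilities.u_smoker_healthy, p.utilities.u_former_healthy
    q = _TOY_Q
    smoker, tunnel, estab = float(n0), 0.0, 0.0
    cost = p.program_costs.initial_cost(arm, n0)
    qalys = 0.0
    prod_total = 0.0
    labour = p.labour
    sex = p.settings.sex
    for t in range(1, _TOY_CYCLES + 1):
        p_quit = tp.p_quit_first_cycle if t == 1 else tp.p_quit_later
        s_surv, t_surv, e_surv = smoker * (1 - q), tunnel * (1 - q), estab * (1 - q)
        new_smoker = (s_surv * (1 - p_quit)
                      + t_surv * tp.p_relapse_after_first_quit_cycle
                      + e_surv * tp.p_relapse_later)
        new_tunnel = s_surv * p_quit
        new_estab = (t_surv * (1 - tp.p_relapse_after_first_quit_cycle)
                     + e_surv * (1 - tp.p_relapse_later))
        smoker, tunnel, estab = new_smoker, new_tunnel, new_estab
        former = tunnel + estab
        age = p.settings.start_age + 0.5 * t
        # disease quantities
        prev_s = min(_TOY_PREV * _TOY_RR_S, 1.0)
        prev_f = min(_TOY_PREV * _TOY_RR_F, 1.0)
        inc_cases = _TOY_INC * _TOY_RR_S * smoker + _TOY_INC * _TOY_RR_F * former
        prev_persons = prev_s * smoker + prev_f * former
        hc = inc_cases * _TOY_COST_INC * 0.5 + prev_persons * _TOY_COST_PREV * 0.5
        # utilities under the lowest-utility rule (single disease)
        u_cycle = (smoker * ((1 - prev_s) * u_s + prev_s * (u_s - _TOY_DEC))
                   + former * ((1 - prev_f) * u_f + prev_f * (u_f - _TOY_DEC))) * 0.5
        # productivity
        emp = labour.employment_fraction(sex, age)
        wage = labour.daily_wage(sex)
        prod = (smoker * emp * labour.sick_days["smoker"] * wage * 0.5
                + former * emp * labour.sick_days["former_smoker"] * wage * 0.5)
        df_c = (1 + r_c) ** (-t * 0.5)
        df_e = (1 + r_e) ** (-t * 0.5)
        cost += hc * df_c
        qalys += u_cycle * df_e
        prod_total += prod * df_c
    if perspective == "societal":
        cost += prod_total
    return {"cost": cost, "qalys": qalys, "productivity": prod_total}


def toy_scenario(sex: str = "male") -> tuple[ParameterSet, dict[str, dict[str, float]]]:
    """3-cycle constant-mortality one-disease scenario plus its oracle ledger.

    Returns the parameter set (both arms included) and a nested dict
    ``expected[arm][perspective]`` of oracle costs/QALYs, with
    ``expected["icur"][perspective]`` for the arm comparison.
    """
    p = _toy_params(sex)
    expected: dict[str, Any] = {}
    for arm in ("combined", "advice"):
        expected[arm] = {persp: _toy_oracle(p, arm, persp)
                         for persp in ("healthcare", "societal")}
    expected["icur"] = {}
    for persp in ("healthcare", "societal"):
        d_cost = expected["combined"][persp]["cost"] - expected["advice"][persp]["cost"]
        d_qaly = expected["combined"][persp]["qalys"] - expected["advice"][persp]["qalys"]
        expected["icur"][persp] = {"delta_cost": d_cost, "delta_qaly": d_qaly,
                                   "icur": d_cost / d_qaly}
    return p, expected
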