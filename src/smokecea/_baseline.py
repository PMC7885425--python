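"""Baseline model inputs for the programme comparison.

The packaged baseline transcribes the published inputs of a Spanish
primary-care smoking-cessation comparison: usual health advice versus the
same advice reinforced by motivational text messages, costed in 2018 euros.
Quantities the source study cites but does not print (age-specific
mortality by smoking status, disease incidence/prevalence schedules,
utility decrements by age) are shipped as clearly labelled *synthetic*
defaults generated by :mod:`smokecea.fixtures`; a config file can
substitute literature values for any of them.

Every numeric baseline field carries a provenance tag (``PROVENANCE``)
naming its origin class:

``trial:*``          effectiveness inputs from the underlying randomized trial
``assumption:*``     stated modelling assumptions (relapse/cessation rates, sick days)
``unit-costs:*``     2018 unit costs (programme items and disease treatment)
``labour:*``         national labour-market statistics
``epi:*``            published relative risks of smoking-related disease
``interpretation:*`` values recovered from ambiguous source typesetting
``synthetic:*``      synthetic default schedules (substitutable)
``settings:*``       analysis settings (discounting, cohort, threshold)
"""

from __future__ import annotations

from typing import Any, Iterator

#: Arms of the comparison. "combined" = advice + text messaging (intervention),
#: "advice" = health advice alone (comparator).
ARMS = ("combined", "advice")

SEXES = ("male", "female")

DISEASES = ("lung_cancer", "myocardial_infarction", "stroke", "copd", "heart_disease")

#: Employment age bands (lower bound inclusive); the last band is open-ended.
EMPLOYMENT_BANDS = ("16-24", "25-34", "35-44", "45-54", "55+")

BASELINE: dict[str, Any] = {
    "settings": {
        "cohort_size": 1000,
        "start_age": 45,
        "sex": "male",
        "cycle_length": 0.5,
        "horizon": "lifetime",
        "discount_rate_costs": 0.03,
        "discount_rate_effects": 0.03,
        "perspective": "healthcare",
        "max_age": 100.0,
    },
    "threshold": 22000.0,
    "transitions": {
        "combined": {
            "p_quit_first_cycle": 0.24375,
            "p_quit_later": 0.02,
            "p_relapse_after_first_quit_cycle": 0.333,
            "p_relapse_later": 0.05,
            "max_quit_attempts_per_year": 2,
        },
        "advice": {
            "p_quit_first_cycle": 0.11875,
            "p_quit_later": 0.02,
            "p_relapse_after_first_quit_cycle": 0.5264,
            "p_relapse_later": 0.05,
            "max_quit_attempts_per_year": 2,
        },
    },
    "utilities": {
        "u_smoker_healthy": 0.75,
        "u_former_healthy": 0.78,
        "comorbidity_rule": "lowest_utility",
    },
    "program_costs": {
        "per_patient": {"combined": 187.90, "advice": 166.95},
        # Itemized components, for reference; the per-patient totals above are
        # authoritative when the two disagree.
        "items": {
            "gp_visit": 58.0,
            "gp_visits_n": 4,
            "nurse_visit": 24.0,
            "nurse_visits_n": 1,
            "nurse_phone": 12.0,
            "nurse_phone_n": 4,
            "messaging_platform": 17385.27,
            "messages_sent": 3127.85,
            "co_monitors": 1891.5,
            "logo": 431.5,
        },
        "training_combined_total": 1900.0,
        # Group size over which one-off per-group items (training) are spread
        # to obtain a per-patient rate.
        "reference_group_size": 1000,
    },
    "labour": {
        "employment": {
            "male": {"16-24": 0.4106, "25-34": 0.9163, "35-44": 0.9405,
                     "45-54": 0.9041, "55+": 0.2801},
            "female": {"16-24": 0.3723, "25-34": 0.8664, "35-44": 0.8438,
                       "45-54": 0.7565, "55+": 0.1807},
        },
        "hourly_wage": {"male": 15.90, "female": 13.60},
        "monthly_agreed_hours": 155.0,
        "sick_days": {"smoker": 11.0, "former_smoker": 7.0},
        # Daily wage = hourly_wage * monthly_agreed_hours * 12 / days_per_year.
        "days_per_year": 365.0,
        # If true, sick-leave losses accrue only to the SRD-prevalent fraction
        # rather than to everyone of a given smoking status.
        "restrict_to_diseased": False,
    },
    "diseases": {
        "lung_cancer": {
            "rr_smoker": {"male": 8.78, "female": 7.48},
            "rr_former": {"male": 3.01, "female": 2.82},
            "cost_incident": 13206.0,
            "cost_prevalent": 13206.0,
            "utility_decrement": 0.25,
        },
        "myocardial_infarction": {
            "rr_smoker": 4.21,
            "rr_former": 1.47,
            "cost_incident": 12987.0,
            "cost_prevalent": 3046.0,
            "utility_decrement": 0.12,
        },
        "stroke": {
            "rr_smoker": 2.58,
            "rr_former": 1.34,
            "cost_incident": 5759.50,
            "cost_prevalent": 3596.60,
            "utility_decrement": 0.15,
        },
        "copd": {
            "rr_smoker": 3.51,
            "rr_former": 2.35,
            "cost_incident": 1672.0,
            "cost_prevalent": 1672.0,
            "utility_decrement": 0.10,
        },
        "heart_disease": {
            "rr_smoker": 4.22,
            "rr_former": 1.51,
            "cost_incident": 8578.0,
            "cost_prevalent": 685.0,
            "utility_decrement": 0.08,
        },
    },
    "calibration": {
        # Daily-smoking prevalence used as the mixture weight when calibrating
        # status-specific mortality to an all-cause life table.
        "smoking_prevalence": 0.34,
    },
    # "synthetic-default" resolves to fixtures.synthetic_life_table /
    # synthetic age schedules at load time; a config may instead give
    # explicit arrays or a CSV path.
    "mortality": {"source": "synthetic-default"},
    "synthetic": {
        "seed": 20180101,
        # Gompertz annual hazard h(a) = intercept * exp(slope * a), fitted
        # loosely to the shape of a modern southern-European life table.
        "gompertz": {
            "male": {"intercept": 5.0e-05, "slope": 0.085},
            "female": {"intercept": 2.5e-05, "slope": 0.088},
        },
        # Hazard ratio of current smokers relative to former smokers.
        "smoker_hazard_ratio": 1.8,
        # Synthetic background (never/former-proxy) annual incidence per
        # person at age 40 and exponential growth per year of age.
        "incidence_at_40": {
            "lung_cancer": 0.0004, "myocardial_infarction": 0.0020,
            "stroke": 0.0015, "copd": 0.0030, "heart_disease": 0.0025,
        },
        "incidence_growth": 0.06,
        "prevalence_at_40": {
            "lung_cancer": 0.004, "myocardial_infarction": 0.020,
            "stroke": 0.015, "copd": 0.040, "heart_disease": 0.030,
        },
        "prevalence_growth": 0.04,
        "prevalence_cap": 0.60,
        # Female background rates relative to male.
        "female_rate_ratio": 0.7,
        "age_min": 16,
        "age_max": 110,
        "band_width": 5,
        "noise_level": 0.0,
    },
}


def _repeat(paths: dict[str, str]) -> dict[str, str]:
    return dict(paths)


PROVENANCE: dict[str, str] = {
    "settings.cohort_size": "settings:cohort-1000-smokers",
    "settings.start_age": "trial:mean-age-45",
    "settings.cycle_length": "settings:6-month-cycles",
    "settings.discount_rate_costs": "settings:discount-3pct",
    "settings.discount_rate_effects": "settings:discount-3pct",
    "settings.max_age": "assumption:horizon-cap-100",
    "threshold": "settings:spanish-nhs-threshold-22000",
    "transitions.combined.p_quit_first_cycle": "trial:quit-6m-combined-24pct",
    "transitions.combined.p_quit_later": "assumption:annual-cessation-2pct-halved",
    "transitions.combined.p_relapse_after_first_quit_cycle": "trial:relapse-combined-33pct",
    "transitions.combined.p_relapse_later": "assumption:annual-relapse-10pct-halved",
    "transitions.combined.max_quit_attempts_per_year": "assumption:two-quit-attempts-per-year",
    "transitions.advice.p_quit_first_cycle": "trial:quit-6m-advice-12pct",
    "transitions.advice.p_quit_later": "assumption:annual-cessation-2pct-halved",
    "transitions.advice.p_relapse_after_first_quit_cycle": "trial:relapse-advice-5264",
    "transitions.advice.p_relapse_later": "assumption:annual-relapse-10pct-halved",
    "transitions.advice.max_quit_attempts_per_year": "assumption:two-quit-attempts-per-year",
    "utilities.u_smoker_healthy": "epi:utility-smoker-no-comorbidity-075",
    "utilities.u_former_healthy": "epi:utility-former-no-comorbidity-078",
    "program_costs.per_patient.combined": "unit-costs:per-patient-combined-18790",
    "program_costs.per_patient.advice": "unit-costs:per-patient-advice-16695",
    "program_costs.items.gp_visit": "unit-costs:gp-visit-58",
    "program_costs.items.gp_visits_n": "unit-costs:gp-visit-58",
    "program_costs.items.nurse_visit": "unit-costs:nurse-visit-24",
    "program_costs.items.nurse_visits_n": "unit-costs:nurse-visit-24",
    "program_costs.items.nurse_phone": "unit-costs:nurse-phone-12",
    "program_costs.items.nurse_phone_n": "unit-costs:nurse-phone-12",
    "program_costs.items.messaging_platform": "unit-costs:messaging-platform",
    "program_costs.items.messages_sent": "unit-costs:messages-sent",
    "program_costs.items.co_monitors": "unit-costs:co-monitors",
    "program_costs.items.logo": "unit-costs:logo",
    "program_costs.training_combined_total": "unit-costs:training-1900",
    "program_costs.reference_group_size": "unit-costs:per-group-divisor-1000",
    "labour.hourly_wage.male": "labour:hourly-earnings-men",
    "labour.hourly_wage.female": "labour:hourly-earnings-women",
    "labour.monthly_agreed_hours": "labour:monthly-agreed-hours-155",
    "labour.sick_days.smoker": "assumption:sick-days-smoker-11",
    "labour.sick_days.former_smoker": "assumption:sick-days-former-7",
    "labour.days_per_year": "assumption:daily-wage-365-divisor",
    "calibration.smoking_prevalence": "epi:daily-smoking-prevalence-34pct",
    "diseases.lung_cancer.rr_smoker.male": "epi:rr-lung-cancer",
    "diseases.lung_cancer.rr_smoker.female": "epi:rr-lung-cancer",
    "diseases.lung_cancer.rr_former.male": "epi:rr-lung-cancer",
    "diseases.lung_cancer.rr_former.female": "epi:rr-lung-cancer",
    "diseases.lung_cancer.cost_incident": "unit-costs:lung-cancer",
    "diseases.lung_cancer.cost_prevalent": "unit-costs:lung-cancer",
    "diseases.lung_cancer.utility_decrement": "synthetic:utility-decrement",
    "diseases.myocardial_infarction.rr_smoker": "interpretation:rr-block",
    "diseases.myocardial_infarction.rr_former": "interpretation:rr-block",
    "diseases.myocardial_infarction.cost_incident": "unit-costs:myocardial-infarction",
    "diseases.myocardial_infarction.cost_prevalent": "unit-costs:myocardial-infarction",
    "diseases.myocardial_infarction.utility_decrement": "synthetic:utility-decrement",
    "diseases.stroke.rr_smoker": "interpretation:rr-block",
    "diseases.stroke.rr_former": "interpretation:rr-block",
    "diseases.stroke.cost_incident": "unit-costs:stroke",
    "diseases.stroke.cost_prevalent": "unit-costs:stroke",
    "diseases.stroke.utility_decrement": "synthetic:utility-decrement",
    "diseases.copd.rr_smoker": "interpretation:rr-block",
    "diseases.copd.rr_former": "interpretation:rr-block",
    "diseases.copd.cost_incident": "unit-costs:copd",
    "diseases.copd.cost_prevalent": "unit-costs:copd",
    "diseases.copd.utility_decrement": "synthetic:utility-decrement",
    "diseases.heart_disease.rr_smoker": "interpretation:rr-block",
    "diseases.heart_disease.rr_former": "interpretation:rr-block",
    "diseases.heart_disease.cost_incident": "unit-costs:heart-disease",
    "diseases.heart_disease.cost_prevalent": "unit-costs:heart-disease",
    "diseases.heart_disease.utility_decrement": "synthetic:utility-decrement",
}

# Employment fractions: one tag per sex x band cell.
for _sex in SEXES:
    for _band in EMPLOYMENT_BANDS:
        PROVENANCE[f"labour.employment.{_sex}.{_band}"] = (
            f"labour:employment-{_sex}-{_band}"
        )

# Synthetic generator parameters are, by definition, synthetic defaults.
def _tag_synthetic(prefix: str, node: Any) -> None:
    if isinstance(node, dict):
        for key, val in node.items():
            _tag_synthetic(f"{prefix}.{key}", val)
    elif isinstance(node, (int, float)):
        PROVENANCE[prefix] = "synthetic:generator-parameter"


_tag_synthetic("synthetic", BASELINE["synthetic"])


def numeric_leaves(node: Any, prefix: str = "") -> Iterator[tuple[str, float]]:
    """Yield (dotted path, value) for every numeric leaf of a config tree."""
    if isinstance(node, dict):
        for key, val in node.items():
            sub = f"{prefix}.{key}" if prefix else str(key)
            yield from numeric_leaves(val, sub)
    elif isinstance(node, bool):
        return
    elif isinstance(node, (int, float)):
        yield prefix, float(node)


def provenance_for(path: str) -> str:
    """Provenance tag for one dotted baseline field path.

    Raises ``KeyError`` for untagged fields; the test suite asserts this
    never happens for the packaged baseline.
    """
    return PROVENANCE[path]
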