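"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from smokecea.parameters import MortalitySchedule, ParameterSet, baseline_parameters


@pytest.fixture
def male_params() -> ParameterSet:
    return baseline_parameters("combined", "male")


@pytest.fixture
def female_params() -> ParameterSet:
    return baseline_parameters("combined", "female")


def zero_mortality(params: ParameterSet) -> ParameterSet:
    """Copy of ``params`` with death probability 0 at every age."""
    p = params.copy()
    ages = np.arange(16.0, 121.0)
    p.mortality = MortalitySchedule(
        ages=ages, q_cycle_smoker=np.zeros_like(ages),
        q_cycle_former=np.zeros_like(ages), source="test-zero-mortality")
    return p


def constant_mortality(params: ParameterSet, q_smoker: float,
                       q_former: float | None = None) -> ParameterSet:
    """Copy of ``params`` with constant per-cycle death probabilities."""
    if q_former is None:
        q_former = q_smoker
    p = params.copy()
    ages = np.arange(16.0, 121.0)
    p.mortality = MortalitySchedule(
        ages=ages, q_cycle_smoker=np.full_like(ages, q_smoker),
        q_cycle_former=np.full_like(ages, q_former),
        source="test-constant-mortality")
    return p


# ---------------------------------------------------------------------------
# exhaustive path-enumeration oracle (independent of the engine's code path)

_STATES = ("smoker", "former_tunnel_1", "former_established", "dead")


def _oracle_tprob(frm: str, to: str, cycle_index: int, age: float,
                  params: ParameterSet, arm: str) -> float:
    """One-step transition probability, written out state by state from the
    model's rules: death first from the status schedule, survivors split by
    the behavioural probabilities."""
    tp = params.transitions[arm]
    q_s = params.mortality.q_cycle("smoker", age)
    q_f = params.mortality.q_cycle("former_smoker", age)
    p_quit = tp.p_quit_first_cycle if cycle_index == 0 else tp.p_quit_later
    rel1 = tp.p_relapse_after_first_quit_cycle
    rel2 = tp.p_relapse_later
    if frm == "smoker":
        return {"smoker": (1 - q_s) * (1 - p_quit),
                "former_tunnel_1": (1 - q_s) * p_quit,
                "former_established": 0.0,
                "dead": q_s}[to]
    if frm == "former_tunnel_1":
        return {"smoker": (1 - q_f) * rel1,
                "former_tunnel_1": 0.0,
                "former_established": (1 - q_f) * (1 - rel1),
                "dead": q_f}[to]
    if frm == "former_established":
        return {"smoker": (1 - q_f) * rel2,
                "former_tunnel_1": 0.0,
                "former_established": (1 - q_f) * (1 - rel2),
                "dead": q_f}[to]
    return 1.0 if to == "dead" else 0.0


def enumerate_occupancy(params: ParameterSet, arm: str, n_cycles: int) -> np.ndarray:
    """Occupancy at cycles 0..n_cycles by brute-force enumeration of every
    state path of the 4-substate chain (feasible for small n_cycles)."""
    start_age = params.settings.start_age
    n = params.settings.cohort_size
    paths = [(("smoker",), 1.0)]
    occ = np.zeros((n_cycles + 1, 4))
    occ[0, 0] = n
    for t in range(n_cycles):
        new_paths = []
        for path, prob in paths:
            frm = path[-1]
            age = start_age + 0.5 * t
            for to in _STATES:
                p_step = _oracle_tprob(frm, to, t, age, params, arm)
                if p_step > 0.0:
                    new_paths.append((path + (to,), prob * p_step))
        paths = new_paths
        for path, prob in paths:
            occ[t + 1, _STATES.index(path[-1])] += n * prob
    return occ
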