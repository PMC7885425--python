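"""Deterministic Markov cohort engine.

Three health states — smoker, former smoker, dead — advanced in 6-month
cycles. The former-smoker state is split into two tunnel substates so the
relapse probability can depend on time since quitting: ``former_tunnel_1``
(quit in the previous cycle, high arm-specific relapse) and
``former_established`` (quit two or more cycles ago, low common relapse).

Within a cycle, death is applied first from the status-specific mortality
schedule; behavioural transitions split the survivors. This keeps every
row of the transition matrix normalized. The cohort is an expected-value
(deterministic) simulation: fractional persons, no Monte Carlo.

Life-years accrue after each transition: survivors of cycle ``t``
contribute 0.5 years, recorded on trace row ``t``. Row 0 is the initial
state and accrues nothing; no half-cycle correction is applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import ParameterSet, ValidationError

__all__ = [
    "STATES",
    "CohortState",
    "CohortTrace",
    "first_cycle_quitters",
    "run_cohort",
    "step_cohort",
    "transition_matrix",
]

#: Substate order used throughout: columns of every occupancy vector/matrix.
STATES = ("smoker", "former_tunnel_1", "former_established", "dead")

_SMOKER, _TUNNEL, _ESTABLISHED, _DEAD = range(4)

#: Extinction threshold: stop once fewer persons than this remain alive.
ALIVE_EPS = 1e-6


@dataclass
class CohortState:
    """Occupancy of the four substates at the start of one cycle."""

    cycle_index: int
    current_age: float
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.occupancy.shape != (4,):
            raise ValidationError("occupancy must be a length-4 vector")
        if np.any(self.occupancy < -1e-9):
            raise ValidationError("occupancies must be nonnegative")

    @property
    def alive(self) -> float:
        return float(self.occupancy[:_DEAD].sum())

    @property
    def total(self) -> float:
        return float(self.occupancy.sum())


def transition_matrix(state: CohortState, params: ParameterSet, arm: str) -> np.ndarray:
    """4x4 row-stochastic transition matrix for the cycle starting at ``state``.

    Smokers quit with the first-cycle probability at cycle 0 and the later
    probability afterwards; the one-cycle tunnel relapses with the
    arm-specific first-cycle relapse probability, established former smokers
    with the common later relapse probability. Death competes first, drawn
    from the status-specific mortality schedule at the current age.
    """
    tp = params.transitions[arm]
    age = state.current_age
    q_s = params.mortality.q_cycle("smoker", age)
    q_f = params.mortality.q_cycle("former_smoker", age)
    p_quit = tp.p_quit_first_cycle if state.cycle_index == 0 else tp.p_quit_later
    rel_1 = tp.p_relapse_after_first_quit_cycle
    rel_2 = tp.p_relapse_later

    m = np.zeros((4, 4))
    m[_SMOKER] = [(1 - q_s) * (1 - p_quit), (1 - q_s) * p_quit, 0.0, q_s]
    m[_TUNNEL] = [(1 - q_f) * rel_1, 0.0, (1 - q_f) * (1 - rel_1), q_f]
    m[_ESTABLISHED] = [(1 - q_f) * rel_2, 0.0, (1 - q_f) * (1 - rel_2), q_f]
    m[_DEAD, _DEAD] = 1.0
    return m


def step_cohort(state: CohortState, params: ParameterSet, arm: str) -> CohortState:
    """Advance the cohort one 6-month cycle."""
    m = transition_matrix(state, params, arm)
    return CohortState(
        cycle_index=state.cycle_index + 1,
        current_age=state.current_age + 0.5,
        occupancy=state.occupancy @ m,
    )


@dataclass
class CohortTrace:
    """Full occupancy history of one cohort run.

    Row ``t`` is the state at the start of cycle ``t`` (equivalently the end
    of cycle ``t-1``); ``life_years[t]`` is the 0.5 years credited to the
    persons alive on row ``t`` (zero on row 0).
    """

    arm: str
    sex: str
    cohort_size: float
    states: list[CohortState] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.states)

    @property
    def cycles(self) -> np.ndarray:
        return np.array([s.cycle_index for s in self.states])

    @property
    def ages(self) -> np.ndarray:
        return np.array([s.current_age for s in self.states])

    @property
    def occupancy(self) -> np.ndarray:
        return np.vstack([s.occupancy for s in self.states])

    @property
    def life_years(self) -> np.ndarray:
        ly = self.occupancy[:, :_DEAD].sum(axis=1) * 0.5
        ly[0] = 0.0
        return ly

    @property
    def total_life_years(self) -> float:
        return float(self.life_years.sum())

    def to_frame(self) -> pd.DataFrame:
        occ = self.occupancy
        return pd.DataFrame({
            "cycle": self.cycles,
            "age": self.ages,
            "smoker": occ[:, _SMOKER],
            "former_tunnel_1": occ[:, _TUNNEL],
            "former_established": occ[:, _ESTABLISHED],
            "dead": occ[:, _DEAD],
            "life_years": self.life_years,
        })

    def conservation_error(self) -> float:
        """Largest absolute deviation of total occupancy from cohort size."""
        return float(np.abs(self.occupancy.sum(axis=1) - self.cohort_size).max())


def run_cohort(params: ParameterSet, arm: str, max_age: float | None = None) -> CohortTrace:
    """Run the cohort from the start age until ``max_age``, the configured
    horizon, or extinction (< 1e-6 persons alive).

    With an all-zero mortality schedule the run cannot converge by
    extinction; it stops at ``max_age`` with a warning.
    """
    settings = params.settings
    if max_age is None:
        max_age = settings.max_age
    if settings.start_age >= max_age:
        raise ValidationError(
            f"start_age {settings.start_age} must be below max_age {max_age}")
    max_cycles = settings.horizon if isinstance(settings.horizon, int) else None

    state = CohortState(
        cycle_index=0,
        current_age=float(settings.start_age),
        occupancy=np.array([float(settings.cohort_size), 0.0, 0.0, 0.0]),
    )
    trace = CohortTrace(arm=arm, sex=settings.sex,
                        cohort_size=float(settings.cohort_size), states=[state])
    while True:
        if max_cycles is not None and state.cycle_index >= max_cycles:
            break
        if state.current_age + 0.5 > max_age + 1e-9:
            # An essentially undepleted cohort at the age cap signals a
            # degenerate (near-zero) mortality schedule.
            if max_cycles is None and state.alive > 0.5 * trace.cohort_size:
                warnings.warn(
                    f"cohort not extinct at max_age={max_age} "
                    f"({state.alive:.3g} persons alive); stopping at horizon cap",
                    RuntimeWarning, stacklevel=2)
            break
        if state.alive < ALIVE_EPS:
            break
        state = step_cohort(state, params, arm)
        trace.states.append(state)
    return trace


def first_cycle_quitters(params: ParameterSet, arm: str, n: float) -> int:
    """Expected number of first-cycle quitters in a cohort of ``n``,
    rounded half-up; mortality is ignored for this short-term summary."""
    if n < 0:
        raise ValidationError("cohort size must be >= 0")
    p = params.transitions[arm].p_quit_first_cycle
    return int(math.floor(n * p + 0.5))
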