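"""Markov cohort engine: transition matrices, cohort traces, outcomes.

The disease process is a discrete-time Markov chain over (FC1, FC2, FC3,
FC4, DEATH) advanced in 3-month cycles. A treated arm's switching
probabilities are the standard-treatment probabilities multiplied by the
drug's relative risks for worsening and improvement; per-class death
probabilities are common to both arms. State membership during cycle k
accrues that cycle's life time, utility and cost, discounted at the
cycle's start with the annual rate compounded in years.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .parameters import (
    BaselineTransitions,
    CostComponents,
    DeathProbabilities,
    EconSettings,
    TreatmentEffect,
    UtilitySet,
    aggregate_direct_medical_cost,
)
from .states import LIVING_STATES, N_STATES, STATE_LABELS, FunctionalClass


class InvalidRowError(ValueError):
    """A transition row's competing probabilities exceed 1 and capping is off."""


@dataclass
class TransitionMatrix:
    """Row-stochastic 5x5 per-cycle matrix for one treatment arm.

    Structure is tridiagonal-plus-death: each living class can only stay,
    move one class up or down, or die; DEATH is absorbing.
    """

    probs: np.ndarray
    drug: Optional[str] = None
    capped_rows: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (N_STATES, N_STATES):
            raise ValueError(f"expected a {N_STATES}x{N_STATES} matrix, got {p.shape}")
        if (p < -1e-12).any() or (p > 1 + 1e-12).any():
            raise InvalidRowError("transition probabilities must lie in [0, 1]")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-12):
            raise InvalidRowError("transition rows must sum to 1")
        self.probs = p


@dataclass
class CohortTrace:
    """State-occupancy fractions of a closed cohort over the horizon."""

    occupancy: np.ndarray  # (horizon_cycles + 1, 5)
    start_state: FunctionalClass
    horizon_cycles: int
    drug: Optional[str] = None

    @property
    def living(self) -> np.ndarray:
        """Total living occupancy per cycle."""
        return self.occupancy[:, : N_STATES - 1].sum(axis=1)


@dataclass
class OutcomeSummary:
    """Lifetime outcome aggregates for one arm."""

    life_years_undiscounted: float
    life_years_discounted: float
    qalys_undiscounted: float
    qalys_discounted: float
    total_cost_undiscounted: float
    total_cost_discounted: float
    perspective: str
    drug: Optional[str] = None


def build_transition_matrix(
    baseline: BaselineTransitions,
    deaths: DeathProbabilities,
    effect: Optional[TreatmentEffect] = None,
    drug: Optional[str] = None,
    cap: bool = True,
) -> TransitionMatrix:
    """Per-cycle matrix for one arm (effect=None means standard treatment).

    For each living class: p(worsen) = baseline worsening x rr_worsening,
    p(improve) = baseline improvement x rr_improvement, p(death) is the
    class death probability unchanged, and p(stay) absorbs the rest. If a
    sampled draw makes worsen+improve+death exceed 1, the excess is removed
    from worsening and improvement proportionally (death untouched) and a
    warning is emitted; with ``cap=False`` such a row raises instead.
    """
    rr_w = effect.rr_worsening.mean if effect is not None else 1.0
    rr_i = effect.rr_improvement.mean if effect is not None else 1.0

    m = np.zeros((N_STATES, N_STATES))
    capped = 0
    for fc in LIVING_STATES:
        i = int(fc)
        worsen = baseline.worsening(fc) * rr_w
        improve = baseline.improvement(fc) * rr_i
        die = deaths[fc].mean
        total_moves = worsen + improve + die
        if total_moves > 1.0:
            if not cap:
                raise InvalidRowError(
                    f"row {STATE_LABELS[i]}: worsen+improve+death = {total_moves:.6g} > 1"
                )
            scale = (1.0 - die) / (worsen + improve)
            warnings.warn(
                f"capped transition row {STATE_LABELS[i]} "
                f"(competing probabilities summed to {total_moves:.4f})",
                RuntimeWarning,
                stacklevel=2,
            )
            worsen *= scale
            improve *= scale
            capped += 1
        if fc is not FunctionalClass.FC4:
            m[i, i + 1] = worsen
        if fc is not FunctionalClass.FC1:
            m[i, i - 1] = improve
        m[i, int(FunctionalClass.DEATH)] = die
        # clamp float dust when a capped row's moves sum to exactly 1 - die
        m[i, i] = max(1.0 - worsen - improve - die, 0.0)
    m[int(FunctionalClass.DEATH), int(FunctionalClass.DEATH)] = 1.0
    return TransitionMatrix(probs=m, drug=drug, capped_rows=capped)


def run_cohort(
    matrix: TransitionMatrix,
    start_state: FunctionalClass,
    horizon_cycles: int,
) -> CohortTrace:
    """Propagate a unit cohort: occupancy(k+1) = occupancy(k) @ matrix."""
    if horizon_cycles < 1:
        raise ValueError(f"horizon_cycles must be >= 1, got {horizon_cycles}")
    if not start_state.is_living:
        raise ValueError("start_state must be a living functional class")
    occ = np.zeros((horizon_cycles + 1, N_STATES))
    occ[0, int(start_state)] = 1.0
    for k in range(horizon_cycles):
        occ[k + 1] = occ[k] @ matrix.probs
    return CohortTrace(
        occupancy=occ,
        start_state=start_state,
        horizon_cycles=horizon_cycles,
        drug=matrix.drug,
    )


def state_cost_vector(
    costs: CostComponents,
    drug: str,
    perspective: str,
    drug_cycle_cost: Optional[float] = None,
) -> np.ndarray:
    """Per-cycle USD cost of occupying each state for one arm.

    Direct medical cost plus the arm's drug cost in every living state
    (including FC IV); household non-medical cost added under the
    societal perspective only; DEATH costs nothing.
    """
    cdrug = costs.drug_cost_per_cycle[drug] if drug_cycle_cost is None else drug_cycle_cost
    vec = np.zeros(N_STATES)
    for fc in LIVING_STATES:
        c = aggregate_direct_medical_cost(costs, fc) + cdrug
        if perspective == "societal":
            c += costs.nonmedical_per_cycle[fc].mean
        vec[int(fc)] = c
    return vec


def accumulate_outcomes(
    trace: CohortTrace,
    utilities: UtilitySet,
    costs: CostComponents,
    drug: str,
    settings: EconSettings,
    drug_cycle_cost: Optional[float] = None,
) -> OutcomeSummary:
    """Discounted and undiscounted life years, QALYs and costs for a trace.

    Cycle k contributes occupancy-at-start-of-cycle times cycle length
    (life), times utility (QALYs), and times the state cost vector,
    discounted by (1+r)^(-k * cycle_length_years). With half-cycle
    correction on, the average of adjacent occupancies is used instead.
    """
    h = trace.horizon_cycles
    dt = settings.cycle_length_years
    r = settings.annual_discount_rate

    if settings.half_cycle_correction:
        occ = 0.5 * (trace.occupancy[:h] + trace.occupancy[1 : h + 1])
    else:
        occ = trace.occupancy[:h]

    k = np.arange(h)
    disc = (1.0 + r) ** (-k * dt)

    u = np.zeros(N_STATES)
    for fc in LIVING_STATES:
        u[int(fc)] = utilities[fc].mean
    cvec = state_cost_vector(costs, drug, settings.perspective, drug_cycle_cost)

    living = occ[:, : N_STATES - 1].sum(axis=1)
    qaly_per_cycle = occ @ u * dt
    cost_per_cycle = occ @ cvec

    return OutcomeSummary(
        life_years_undiscounted=float(living.sum() * dt),
        life_years_discounted=float((living * disc).sum() * dt),
        qalys_undiscounted=float(qaly_per_cycle.sum()),
        qalys_discounted=float((qaly_per_cycle * disc).sum()),
        total_cost_undiscounted=float(cost_per_cycle.sum()),
        total_cost_discounted=float((cost_per_cycle * disc).sum()),
        perspective=settings.perspective,
        drug=drug,
    )


def choose_horizon(
    matrix: Optional[TransitionMatrix],
    start_state: Optional[FunctionalClass],
    mode: str,
    settings: Optional[EconSettings] = None,
    max_cycles: int = 4000,
) -> int:
    """Resolve a lifetime horizon in cycles.

    mode 'fixed:N' returns N; 'extinction:eps' returns the first cycle at
    which living occupancy drops below eps; 'calibrated' returns the
    bundled calibrated horizon from the settings.
    """
    if mode.startswith("fixed:"):
        n = int(mode.split(":", 1)[1])
        if n < 1:
            raise ValueError("fixed horizon must be >= 1")
        return n
    if mode.startswith("extinction:"):
        eps = float(mode.split(":", 1)[1])
        if eps <= 0:
            raise ValueError("extinction epsilon must be > 0")
        if matrix is None or start_state is None:
            raise ValueError("extinction mode needs a matrix and start state")
        occ = np.zeros(N_STATES)
        occ[int(start_state)] = 1.0
        for k in range(1, max_cycles + 1):
            occ = occ @ matrix.probs
            if occ[: N_STATES - 1].sum() < eps:
                return k
        raise RuntimeError(f"cohort not extinct within {max_cycles} cycles")
    if mode == "calibrated":
        if settings is None:
            raise ValueError("calibrated mode needs settings")
        return settings.horizon_cycles
    raise ValueError(f"unknown horizon mode {mode!r}")
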