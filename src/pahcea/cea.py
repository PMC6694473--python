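"""Base-case cost-utility comparison: incremental cost, QALYs, ICER, NMB.

Sildenafil (intervention) is compared against beraprost (comparator)
from a common starting functional class. The ICER is the incremental
discounted cost divided by the incremental discounted QALYs; a strategy
is cost-effective at a willingness-to-pay (WTP) threshold when its ICER
falls below the threshold, or when it dominates (cheaper and more
effective).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional

from .markov import (
    OutcomeSummary,
    accumulate_outcomes,
    build_transition_matrix,
    run_cohort,
)
from .parameters import ParameterSet
from .states import FunctionalClass

INTERVENTION = "sildenafil"
COMPARATOR = "beraprost"


@dataclass
class CEResult:
    start_state: FunctionalClass
    outcomes: Dict[str, OutcomeSummary]
    incremental_cost: float
    incremental_qaly: float
    icer: float  # nan when incremental QALYs are zero
    nmb_difference: float
    cost_effective: bool
    status: str  # 'icer', 'dominant', 'dominated', 'indifferent'


def net_monetary_benefit(outcome: OutcomeSummary, wtp: float) -> float:
    """wtp x discounted QALYs - discounted cost."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * outcome.qalys_discounted - outcome.total_cost_discounted


def evaluate_arm(
    params: ParameterSet,
    drug: str,
    start_state: FunctionalClass,
    drug_cycle_cost: Optional[float] = None,
    horizon_cycles: Optional[int] = None,
) -> OutcomeSummary:
    """Deterministic run of one arm at the parameter means."""
    matrix = build_transition_matrix(
        params.transitions, params.deaths, params.effects[drug], drug=drug
    )
    h = horizon_cycles if horizon_cycles is not None else params.settings.horizon_cycles
    trace = run_cohort(matrix, start_state, h)
    return accumulate_outcomes(
        trace, params.utilities, params.costs, drug, params.settings,
        drug_cycle_cost=drug_cycle_cost,
    )


def run_base_case(
    params: ParameterSet,
    start_state: FunctionalClass,
    price_scenario: str = "generic",
    price_multiplier: float = 1.0,
) -> CEResult:
    """Deterministic two-arm comparison at parameter means.

    ``price_scenario`` / ``price_multiplier`` reprice the sildenafil
    per-cycle drug cost (see CostComponents.sildenafil_cycle_cost);
    beraprost is always at its listed price.
    """
    if start_state not in (FunctionalClass.FC2, FunctionalClass.FC3):
        raise ValueError("the model starts cohorts in FC II or FC III")
    sil_cost = params.costs.sildenafil_cycle_cost(price_scenario, price_multiplier)
    outcomes = {
        INTERVENTION: evaluate_arm(params, INTERVENTION, start_state, drug_cycle_cost=sil_cost),
        COMPARATOR: evaluate_arm(params, COMPARATOR, start_state),
    }
    return compare_outcomes(outcomes, params.settings.wtp_per_qaly, start_state)


def compare_outcomes(
    outcomes: Dict[str, OutcomeSummary],
    wtp: float,
    start_state: FunctionalClass,
) -> CEResult:
    """Incremental statistics for intervention vs comparator outcomes."""
    oi, oc = outcomes[INTERVENTION], outcomes[COMPARATOR]
    d_cost = oi.total_cost_discounted - oc.total_cost_discounted
    d_qaly = oi.qalys_discounted - oc.qalys_discounted
    nmb_diff = net_monetary_benefit(oi, wtp) - net_monetary_benefit(oc, wtp)

    if d_qaly == 0.0 and d_cost == 0.0:
        status, icer, ce = "indifferent", math.nan, False
    elif d_qaly == 0.0:
        status, icer, ce = ("dominated" if d_cost > 0 else "dominant"), math.nan, d_cost < 0
    elif d_qaly > 0 and d_cost <= 0:
        status, icer, ce = "dominant", d_cost / d_qaly, True
    elif d_qaly < 0 and d_cost >= 0:
        status, icer, ce = "dominated", d_cost / d_qaly, False
    else:
        icer = d_cost / d_qaly
        status = "icer"
        ce = d_qaly > 0 and icer <= wtp
    return CEResult(
        start_state=start_state,
        outcomes=outcomes,
        incremental_cost=d_cost,
        incremental_qaly=d_qaly,
        icer=icer,
        nmb_difference=nmb_diff,
        cost_effective=ce,
        status=status,
    )
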