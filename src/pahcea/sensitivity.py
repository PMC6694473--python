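"""Uncertainty analysis: probabilistic SA, CEAC, one-way SA, threshold price.

The probabilistic sensitivity analysis (PSA) redraws every uncertain
input from its method-of-moments distribution and re-evaluates both
treatment arms per draw. Parameters shared between arms (baseline
switching, death probabilities, costs, utilities) use common random
numbers within a draw; only the relative risks are arm-specific. The
cost-effectiveness acceptability curve (CEAC) reports, per WTP value,
the fraction of draws in which each arm has the higher net monetary
benefit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cea import COMPARATOR, INTERVENTION, CEResult, compare_outcomes, run_base_case
from .markov import accumulate_outcomes, build_transition_matrix, run_cohort
from .moments import MomentSpec
from .parameters import (
    ClassMoments,
    ParameterSet,
    parameter_set_from_dict,
)
from .states import FunctionalClass


def _draw_spec(spec: MomentSpec, rng: np.random.Generator, clip_unit: bool = False) -> MomentSpec:
    """One draw from a MomentSpec, returned as a degenerate (fixed) spec."""
    value = float(spec.sample(rng))
    if clip_unit:
        value = min(max(value, 0.0), 1.0)
    return MomentSpec(mean=value, se=0.0, family="fixed")


def _draw_class(cm: ClassMoments, rng: np.random.Generator, clip_unit: bool = False) -> ClassMoments:
    return ClassMoments(
        fc1=_draw_spec(cm.fc1, rng, clip_unit),
        fc2=_draw_spec(cm.fc2, rng, clip_unit),
        fc3=_draw_spec(cm.fc3, rng, clip_unit),
        fc4=_draw_spec(cm.fc4, rng, clip_unit),
    )


def sample_parameter_set(params: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """One PSA realization of the full parameter set.

    Each non-fixed parameter is drawn independently from its fitted
    distribution; fixed quantities (per-cycle drug costs, unit prices)
    pass through. Beta draws lie in [0, 1] by construction; transition
    rows that sum past 1 after the relative risks are applied are
    handled by the engine's capping rule, not here.
    """
    t, d, c, u = params.transitions, params.deaths, params.costs, params.utilities
    realization = params.model_copy(
        update={
            "transitions": t.model_copy(
                update={k: _draw_spec(getattr(t, k), rng) for k in type(t).model_fields}
            ),
            "deaths": d.model_copy(
                update={k: _draw_spec(getattr(d, k), rng) for k in type(d).model_fields}
            ),
            "effects": {
                drug: eff.model_copy(
                    update={
                        "rr_worsening": _draw_spec(eff.rr_worsening, rng),
                        "rr_improvement": _draw_spec(eff.rr_improvement, rng),
                    }
                )
                for drug, eff in params.effects.items()
            },
            "costs": c.model_copy(
                update={
                    "admissions_per_cycle": _draw_class(c.admissions_per_cycle, rng),
                    "visits_per_cycle": _draw_class(c.visits_per_cycle, rng),
                    "cost_per_admission": _draw_spec(c.cost_per_admission, rng),
                    "cost_per_visit": _draw_spec(c.cost_per_visit, rng),
                    "nonmedical_per_cycle": _draw_class(c.nonmedical_per_cycle, rng),
                }
            ),
            "utilities": u.model_copy(
                update={k: _draw_spec(getattr(u, k), rng) for k in ("fc1", "fc2", "fc3", "fc4")}
            ),
        }
    )
    return realization


@dataclass
class PSADraw:
    """One Monte-Carlo evaluation of both arms under a common realization."""

    index: int
    cost: Dict[str, float]  # discounted, per arm
    qaly: Dict[str, float]  # discounted, per arm
    capped_rows: int


def run_psa(
    params: ParameterSet,
    start_state: FunctionalClass,
    n_draws: int = 1000,
    seed: int = 0,
) -> List[PSADraw]:
    """Monte-Carlo PSA: ``n_draws`` paired evaluations of both arms.

    Draw ``i`` is reproducible in isolation: its generator is seeded from
    (seed, i), so the same (seed, index) always yields the same
    realization regardless of batch size.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    settings = params.settings
    draws: List[PSADraw] = []
    for i in range(n_draws):
        rng = np.random.default_rng([seed, i])
        realization = sample_parameter_set(params, rng)
        cost, qaly = {}, {}
        capped = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for drug in (INTERVENTION, COMPARATOR):
                matrix = build_transition_matrix(
                    realization.transitions, realization.deaths,
                    realization.effects[drug], drug=drug,
                )
                capped += matrix.capped_rows
                trace = run_cohort(matrix, start_state, settings.horizon_cycles)
                out = accumulate_outcomes(
                    trace, realization.utilities, realization.costs, drug, settings
                )
                cost[drug] = out.total_cost_discounted
                qaly[drug] = out.qalys_discounted
        draws.append(PSADraw(index=i, cost=cost, qaly=qaly, capped_rows=capped))
    return draws


@dataclass
class CEACCurve:
    wtp: np.ndarray
    probability: Dict[str, np.ndarray]  # per arm, sums to 1 across arms
    n_draws: int


def compute_ceac(draws: Sequence[PSADraw], wtp_grid: Sequence[float]) -> CEACCurve:
    """Probability each arm is cost-effective over a WTP grid (ties split)."""
    if len(draws) == 0:
        raise ValueError("compute_ceac needs at least one draw")
    wtp = np.asarray(list(wtp_grid), dtype=float)
    if (wtp < 0).any():
        raise ValueError("WTP grid must be nonnegative")
    cost_i = np.array([d.cost[INTERVENTION] for d in draws])
    cost_c = np.array([d.cost[COMPARATOR] for d in draws])
    qaly_i = np.array([d.qaly[INTERVENTION] for d in draws])
    qaly_c = np.array([d.qaly[COMPARATOR] for d in draws])
    # NMB difference per (draw, wtp)
    diff = (qaly_i - qaly_c)[:, None] * wtp[None, :] - (cost_i - cost_c)[:, None]
    wins = (diff > 0).mean(axis=0) + 0.5 * (diff == 0).mean(axis=0)
    return CEACCurve(
        wtp=wtp,
        probability={INTERVENTION: wins, COMPARATOR: 1.0 - wins},
        n_draws=len(draws),
    )


def probability_cost_effective(draws: Sequence[PSADraw], wtp: float) -> Dict[str, float]:
    """Fraction of draws where each arm has the higher NMB at one WTP."""
    curve = compute_ceac(draws, [wtp])
    return {arm: float(p[0]) for arm, p in curve.probability.items()}


# ---------------------------------------------------------------------------
# one-way (deterministic) sensitivity analysis

#: (label, section, field) triples of every scalar MomentSpec in the model.
def _named_specs(params: ParameterSet) -> List[Tuple[str, Tuple[str, ...]]]:
    names: List[Tuple[str, Tuple[str, ...]]] = []
    for f in type(params.transitions).model_fields:
        names.append((f"transition {f}", ("transitions", f)))
    for f in ("fc1", "fc2", "fc3", "fc4"):
        names.append((f"death probability {f}", ("deaths", f)))
    for drug in params.effects:
        names.append((f"{drug} RR worsening", ("effects", drug, "rr_worsening")))
        names.append((f"{drug} RR improvement", ("effects", drug, "rr_improvement")))
    for f in ("fc1", "fc2", "fc3", "fc4"):
        names.append((f"admissions {f}", ("costs", "admissions_per_cycle", f)))
    for f in ("fc1", "fc2", "fc3"):
        names.append((f"visits {f}", ("costs", "visits_per_cycle", f)))
    names.append(("cost per admission", ("costs", "cost_per_admission")))
    names.append(("cost per visit", ("costs", "cost_per_visit")))
    for f in ("fc1", "fc2", "fc3", "fc4"):
        names.append((f"nonmedical cost {f}", ("costs", "nonmedical_per_cycle", f)))
    for f in ("fc1", "fc2", "fc3", "fc4"):
        names.append((f"utility {f}", ("utilities", f)))
    return names


def _with_mean(params: ParameterSet, path: Tuple[str, ...], value: float) -> ParameterSet:
    doc = params.model_dump(mode="json")
    node = doc
    for key in path[:-1]:
        node = node[key]
    node[path[-1]] = dict(node[path[-1]], mean=value, se=0.0, family="fixed")
    return parameter_set_from_dict(doc)


def _bounds(spec: MomentSpec, z: float) -> Tuple[float, float, bool]:
    """mean +/- z*se clipped to the family's domain; flag True if clipped."""
    lo, hi = spec.mean - z * spec.se, spec.mean + z * spec.se
    clipped = False
    if spec.family == "beta":
        if lo < 0.0 or hi > 1.0:
            clipped = True
        lo, hi = max(lo, 0.0), min(hi, 1.0)
    elif spec.family in ("gamma", "lognormal"):
        if lo < 0.0:
            clipped = True
        lo = max(lo, 1e-9 if spec.family == "lognormal" else 0.0)
    return lo, hi, clipped


def one_way_analysis(
    params: ParameterSet,
    start_state: FunctionalClass,
    parameters: Optional[Sequence[Tuple[str, Tuple[str, ...]]]] = None,
    z: float = 1.96,
) -> pd.DataFrame:
    """Tornado table: ICER at each parameter's low/high bound, others at means.

    Default range is mean +/- 1.96 SE clipped to the family's domain;
    rows are sorted by the ICER swing |high - low|, largest first.
    """
    base = run_base_case(params, start_state)
    rows = []
    for label, path in parameters if parameters is not None else _named_specs(params):
        node: object = params
        for key in path:
            node = node[key] if isinstance(node, dict) else getattr(node, key)
        spec: MomentSpec = node  # type: ignore[assignment]
        lo, hi, clipped = _bounds(spec, z)
        if clipped:
            warnings.warn(f"range for {label} clipped to its domain", RuntimeWarning)
        icer_lo = run_base_case(_with_mean(params, path, lo), start_state).icer
        icer_hi = run_base_case(_with_mean(params, path, hi), start_state).icer
        swing = abs(icer_hi - icer_lo) if math.isfinite(icer_hi - icer_lo) else math.inf
        rows.append(
            {
                "parameter": label,
                "low": lo,
                "high": hi,
                "icer_low": icer_lo,
                "icer_high": icer_hi,
                "swing": swing,
                "clipped": clipped,
            }
        )
    table = pd.DataFrame(rows)
    table["icer_base"] = base.icer
    return table.sort_values("swing", ascending=False).reset_index(drop=True)


def price_scenario_icers(params: ParameterSet, start_state: FunctionalClass) -> Dict[str, float]:
    """ICER at generic vs originator sildenafil price and their ratio."""
    generic = run_base_case(params, start_state, price_scenario="generic").icer
    originator = run_base_case(params, start_state, price_scenario="originator").icer
    return {"generic": generic, "originator": originator, "ratio": originator / generic}


# ---------------------------------------------------------------------------
# threshold price analysis

@dataclass
class ThresholdResult:
    multiplier: float
    percent_reduction: float
    icer_at_multiplier: float
    wtp: float


def threshold_price_search(
    params: ParameterSet,
    wtp: Optional[float] = None,
    start_states: Sequence[FunctionalClass] = (FunctionalClass.FC2, FunctionalClass.FC3),
    icer_tol: float = 1.0,
) -> ThresholdResult:
    """Originator price multiplier at which sildenafil becomes cost-effective.

    Bisects the multiplier on the originator tablet price (the per-cycle
    drug cost scales linearly) until the binding ICER — the maximum over
    the requested starting classes — equals the WTP within ``icer_tol``
    USD/QALY. Returns multiplier 1 (0% reduction) if already
    cost-effective at full price.
    """
    wtp_v = params.settings.wtp_per_qaly if wtp is None else wtp

    def binding_icer(mult: float) -> float:
        icers = []
        for s in start_states:
            res = run_base_case(params, s, price_scenario="originator", price_multiplier=mult)
            # a dominant intervention counts as far below any threshold
            icers.append(res.icer if res.incremental_qaly > 0 else math.inf)
        return max(icers)

    if binding_icer(1.0) <= wtp_v:
        return ThresholdResult(1.0, 0.0, binding_icer(1.0), wtp_v)

    lo, hi = 1e-6, 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        icer = binding_icer(mid)
        if abs(icer - wtp_v) < icer_tol:
            return ThresholdResult(mid, 100.0 * (1.0 - mid), icer, wtp_v)
        if icer > wtp_v:
            hi = mid
        else:
            lo = mid
    raise RuntimeError("threshold price search did not converge")
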