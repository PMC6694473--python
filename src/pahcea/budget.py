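"""Five-year open-cohort budget-impact projection (payer perspective).

The eligible population is a prevalent pool split 50/50 between FC II
and FC III plus an annual incident cohort with the same split. Every
cohort is traced quarterly through the arm's Markov model; the annual
budget is the occupancy-weighted sum of direct medical plus drug cost
(the government pays no household non-medical cost), undiscounted by
default as is standard for budget-impact analyses. Deaths attrite the
pool; incident cohorts enter at the start of each year, including
year 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .markov import build_transition_matrix, state_cost_vector
from .parameters import EpiInputs, ParameterSet
from .states import N_STATES, FunctionalClass

ARMS = ("beraprost", "sildenafil")
START_CLASSES = (FunctionalClass.FC2, FunctionalClass.FC3)


def project_budget(
    params: ParameterSet,
    epi: EpiInputs,
    drug: str,
    start_fc: FunctionalClass,
    years: int = 5,
    discount_rate: float = 0.0,
) -> np.ndarray:
    """Annual payer budget (USD) for one arm and starting class.

    Year 1 enrols the prevalent pool (prevalence x class fraction) plus,
    if configured, the year-1 incident cohort; each later year adds an
    incident cohort (annual incidence x class fraction). All patients
    enter in ``start_fc`` and are traced with the arm's transition
    matrix in 3-month cycles.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    frac = {FunctionalClass.FC2: epi.fc2_fraction, FunctionalClass.FC3: epi.fc3_fraction}[start_fc]
    matrix = build_transition_matrix(params.transitions, params.deaths, params.effects[drug], drug=drug)
    cvec = state_cost_vector(params.costs, drug, perspective="government")

    occ = np.zeros(N_STATES)
    annual = np.zeros(years)
    cycles_per_year = int(round(1.0 / params.settings.cycle_length_years))
    for year in range(years):
        if year == 0:
            occ[int(start_fc)] += epi.prevalence * frac
            if epi.include_year1_incidence:
                occ[int(start_fc)] += epi.annual_incidence * frac
        else:
            occ[int(start_fc)] += epi.annual_incidence * frac
        for q in range(cycles_per_year):
            k = year * cycles_per_year + q
            disc = (1.0 + discount_rate) ** (-(k * params.settings.cycle_length_years))
            annual[year] += float(occ @ cvec) * disc
            occ = occ @ matrix.probs
    return annual


@dataclass
class BudgetTable:
    """Per-year, per-arm budgets for both starting classes, in USD."""

    years: np.ndarray  # 1..N
    columns: Dict[str, np.ndarray]  # keys like 'FC2/beraprost'

    def totals(self) -> Dict[str, float]:
        return {k: float(v.sum()) for k, v in self.columns.items()}

    def to_frame(self, millions: bool = False) -> pd.DataFrame:
        scale = 1e-6 if millions else 1.0
        df = pd.DataFrame({k: v * scale for k, v in self.columns.items()},
                          index=pd.Index(self.years, name="year"))
        df.loc["total"] = df.sum(axis=0)
        return df


def build_budget_table(
    params: ParameterSet,
    epi: Optional[EpiInputs] = None,
    years: int = 5,
    discount_rate: float = 0.0,
) -> BudgetTable:
    """Project all four arm x starting-class columns."""
    epi = params.epidemiology if epi is None else epi
    cols: Dict[str, np.ndarray] = {}
    for fc in START_CLASSES:
        for drug in ARMS:
            cols[f"{fc.name}/{drug}"] = project_budget(
                params, epi, drug, fc, years=years, discount_rate=discount_rate
            )
    return BudgetTable(years=np.arange(1, years + 1), columns=cols)


def incremental_budget(table: BudgetTable) -> Dict[str, float]:
    """Five-year incremental (sildenafil - beraprost) budget per class and combined."""
    lengths = {len(v) for v in table.columns.values()}
    if len(lengths) != 1:
        raise ValueError("budget columns cover mismatched year ranges")
    out: Dict[str, float] = {}
    combined = 0.0
    for fc in START_CLASSES:
        inc = float(
            table.columns[f"{fc.name}/sildenafil"].sum()
            - table.columns[f"{fc.name}/beraprost"].sum()
        )
        out[fc.name] = inc
        combined += inc
    out["combined"] = combined
    return out
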