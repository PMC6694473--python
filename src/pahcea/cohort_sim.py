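"""Synthetic patient-level microdata and parameter re-estimation.

The cost and utility inputs of the model were estimated from a small
interview/billing sample (48 patients: 18 FC I, 19 FC II, 10 FC III,
1 FC IV). This module generates patient records with that structure —
per-patient 3-month admission and outpatient-visit counts, unit costs,
household non-medical cost, and an EQ-5D utility — and re-estimates the
per-class means and standard errors from them, closing the loop from
raw-data structure to model inputs. Counts are drawn Poisson at the
per-class mean (nonnegative, integer-valued); monetary amounts from the
fitted gammas; utilities from the fitted betas. Utilities are sampled
directly rather than through EQ-5D dimension responses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .moments import MomentSpec
from .parameters import ClassMoments, ParameterSet, parameter_set_from_dict
from .states import LIVING_STATES, FunctionalClass

DEFAULT_N_PER_FC: Tuple[int, int, int, int] = (18, 19, 10, 1)

RECORD_COLUMNS = (
    "patient_id",
    "functional_class",
    "admissions",
    "visits",
    "admission_cost",
    "visit_cost",
    "nonmedical_cost",
    "utility",
)


def generate_cohort(
    truth: ParameterSet,
    n_per_fc: Sequence[int] = DEFAULT_N_PER_FC,
    seed: int = 0,
) -> pd.DataFrame:
    """Patient records per class, reproducible from ``seed``.

    Columns: patient_id; functional_class (FC1..FC4); admissions and
    visits (counts per 3 months); admission_cost and visit_cost (USD per
    event); nonmedical_cost (USD per 3 months); utility in [0, 1].
    """
    if len(n_per_fc) != 4 or any(n < 0 for n in n_per_fc):
        raise ValueError("n_per_fc must be four nonnegative counts")
    rng = np.random.default_rng(seed)
    c, u = truth.costs, truth.utilities
    rows = []
    pid = 0
    for fc, n in zip(LIVING_STATES, n_per_fc):
        for _ in range(n):
            visits_spec = c.visits_per_cycle[fc]
            rows.append(
                {
                    "patient_id": pid,
                    "functional_class": fc.name,
                    "admissions": int(rng.poisson(c.admissions_per_cycle[fc].mean)),
                    "visits": int(rng.poisson(visits_spec.mean)) if visits_spec.mean > 0 else 0,
                    "admission_cost": float(c.cost_per_admission.sample(rng)),
                    "visit_cost": float(c.cost_per_visit.sample(rng)),
                    "nonmedical_cost": float(c.nonmedical_per_cycle[fc].sample(rng)),
                    "utility": float(min(max(u[fc].sample(rng), 0.0), 1.0)),
                }
            )
            pid += 1
    return pd.DataFrame(rows, columns=list(RECORD_COLUMNS))


@dataclass
class EstimatedMoments:
    """Sample means/SEs per class plus pooled unit costs.

    per_class maps parameter -> class name -> (mean, se, n); the SE is
    the sample SD over sqrt(n) and is NaN when n < 2 (a single FC IV
    patient leaves its SE undefined, as in the source data).
    """

    per_class: Dict[str, Dict[str, Tuple[float, float, int]]]
    pooled: Dict[str, Tuple[float, float, int]]

    def as_config_sections(self) -> Dict[str, dict]:
        """Emit cost/utility sections in the parameter-config schema."""

        def spec(mean: float, se: float, family: str) -> dict:
            return {"mean": float(mean), "se": float(se) if math.isfinite(se) else 0.0,
                    "family": family}

        def per_class(param: str, family: str) -> dict:
            return {
                fc: spec(m, s, family if (math.isfinite(s) and s > 0) else "fixed")
                for fc, (m, s, _n) in self.per_class[param].items()
            }

        return {
            "costs": {
                "admissions_per_cycle": per_class("admissions", "gamma"),
                "visits_per_cycle": per_class("visits", "gamma"),
                "cost_per_admission": spec(*self.pooled["admission_cost"][:2], "gamma"),
                "cost_per_visit": spec(*self.pooled["visit_cost"][:2], "gamma"),
                "nonmedical_per_cycle": per_class("nonmedical_cost", "gamma"),
            },
            "utilities": per_class("utility", "beta"),
        }


def estimate_parameters(records: pd.DataFrame) -> EstimatedMoments:
    """Per-class sample means and standard errors from patient records."""
    if len(records) == 0:
        raise ValueError("cannot estimate parameters from an empty cohort")
    per_class: Dict[str, Dict[str, Tuple[float, float, int]]] = {}
    for param in ("admissions", "visits", "nonmedical_cost", "utility"):
        per_class[param] = {}
        for fc_name, group in records.groupby("functional_class"):
            x = group[param].to_numpy(dtype=float)
            n = len(x)
            mean = float(x.mean())
            se = float(x.std(ddof=1) / math.sqrt(n)) if n >= 2 else math.nan
            per_class[param][fc_name.lower()] = (mean, se, n)
    pooled: Dict[str, Tuple[float, float, int]] = {}
    for param in ("admission_cost", "visit_cost"):
        x = records[param].to_numpy(dtype=float)
        n = len(x)
        se = float(x.std(ddof=1) / math.sqrt(n)) if n >= 2 else math.nan
        pooled[param] = (float(x.mean()), se, n)
    return EstimatedMoments(per_class=per_class, pooled=pooled)


def refit_parameter_set(base: ParameterSet, estimates: EstimatedMoments) -> ParameterSet:
    """Replace cost/utility means (and available SEs) in a parameter set.

    Transition, death and treatment-effect inputs come from literature,
    not the patient sample, so they are kept from ``base``. Classes with
    an undefined SE keep the base SE.
    """
    doc = base.model_dump(mode="json")
    est = estimates.as_config_sections()

    def merge_spec(target: dict, mean: float, se) -> None:
        target["mean"] = mean
        if se is not None and se > 0:
            target["se"] = se

    for param, section in (
        ("admissions", "admissions_per_cycle"),
        ("visits", "visits_per_cycle"),
        ("nonmedical_cost", "nonmedical_per_cycle"),
    ):
        for fc, (mean, se, _n) in estimates.per_class[param].items():
            merge_spec(doc["costs"][section][fc], mean, se if math.isfinite(se) else None)
    for fc, (mean, se, _n) in estimates.per_class["utility"].items():
        merge_spec(doc["utilities"][fc], min(max(mean, 0.0), 1.0),
                   se if math.isfinite(se) else None)
    for param, key in (("admission_cost", "cost_per_admission"), ("visit_cost", "cost_per_visit")):
        mean, se, _n = estimates.pooled[param]
        merge_spec(doc["costs"][key], mean, se if math.isfinite(se) else None)
    return parameter_set_from_dict(doc)
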