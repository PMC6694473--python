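"""Model parameter containers, validation, and YAML (de)serialization.

The whole evaluation is driven by one configuration document with
sections ``transitions``, ``deaths``, ``effects``, ``costs``,
``utilities``, ``settings`` and ``epidemiology``. Every uncertain entry
is a ``{mean, se, family}`` triple (see :mod:`pahcea.moments`). The
bundled ``data/table1.yaml`` is the canonical parameterization of the
Indonesian PAH evaluation: per-cycle functional-class switching and
death probabilities under standard treatment, drug relative risks,
per-class resource use and unit costs, household (non-medical) costs,
utilities, and the economic settings (3-month cycle, 3% annual
discount, WTP one GDP per capita = USD 3109).
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Dict, Optional

import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from .moments import MomentSpec
from .states import FunctionalClass

DRUGS = ("sildenafil", "beraprost")


class ClassMoments(BaseModel):
    """One MomentSpec per living functional class."""

    fc1: MomentSpec
    fc2: MomentSpec
    fc3: MomentSpec
    fc4: MomentSpec

    def __getitem__(self, fc: FunctionalClass) -> MomentSpec:
        return getattr(self, fc.key)

    def means(self) -> dict[str, float]:
        return {k: getattr(self, k).mean for k in ("fc1", "fc2", "fc3", "fc4")}


class BaselineTransitions(BaseModel):
    """Per-cycle FC switching probabilities under standard treatment.

    Only adjacent moves exist: worsening FCi -> FCi+1 and improvement
    FCi -> FCi-1. FC I cannot improve; FC IV cannot worsen.
    """

    fc1_to_fc2: MomentSpec
    fc2_to_fc1: MomentSpec
    fc2_to_fc3: MomentSpec
    fc3_to_fc2: MomentSpec
    fc3_to_fc4: MomentSpec
    fc4_to_fc3: MomentSpec

    def worsening(self, fc: FunctionalClass) -> float:
        return {
            FunctionalClass.FC1: self.fc1_to_fc2.mean,
            FunctionalClass.FC2: self.fc2_to_fc3.mean,
            FunctionalClass.FC3: self.fc3_to_fc4.mean,
            FunctionalClass.FC4: 0.0,
        }[fc]

    def improvement(self, fc: FunctionalClass) -> float:
        return {
            FunctionalClass.FC1: 0.0,
            FunctionalClass.FC2: self.fc2_to_fc1.mean,
            FunctionalClass.FC3: self.fc3_to_fc2.mean,
            FunctionalClass.FC4: self.fc4_to_fc3.mean,
        }[fc]


class DeathProbabilities(BaseModel):
    """Per-cycle death probability from each functional class (both arms)."""

    fc1: MomentSpec
    fc2: MomentSpec
    fc3: MomentSpec
    fc4: MomentSpec

    def __getitem__(self, fc: FunctionalClass) -> MomentSpec:
        return getattr(self, fc.key)


class TreatmentEffect(BaseModel):
    """Multiplicative relative risks on the baseline switching probabilities."""

    rr_worsening: MomentSpec
    rr_improvement: MomentSpec

    @model_validator(mode="after")
    def _positive(self) -> "TreatmentEffect":
        if self.rr_worsening.mean <= 0 or self.rr_improvement.mean <= 0:
            raise ValueError("relative risks must be positive")
        return self


class CostComponents(BaseModel):
    """Resource use and unit costs, all USD per 3-month cycle where rates.

    Direct medical cost of a class excludes the pulmonary selective drug,
    which is added per arm; FC IV patients accrue admissions only (no
    outpatient visits). Non-medical cost is the household expense
    (travel, consumption, accommodation, caregiver time) counted under
    the societal perspective only.
    """

    admissions_per_cycle: ClassMoments
    visits_per_cycle: ClassMoments
    cost_per_admission: MomentSpec
    cost_per_visit: MomentSpec
    nonmedical_per_cycle: ClassMoments
    drug_cost_per_cycle: Dict[str, float]
    tablet_price: Dict[str, float] = Field(
        default_factory=lambda: {
            "sildenafil_generic": 0.34,
            "sildenafil_originator": 2.18,
            "beraprost": 0.33,
        }
    )
    tablets_per_cycle: int = 270

    @model_validator(mode="after")
    def _nonneg(self) -> "CostComponents":
        for drug, c in self.drug_cost_per_cycle.items():
            if c < 0:
                raise ValueError(f"drug_cost_per_cycle[{drug}] must be >= 0")
        return self

    def sildenafil_cycle_cost(self, scenario: str = "generic", multiplier: float = 1.0) -> float:
        """Per-cycle sildenafil cost under a price scenario.

        'generic' uses the listed per-cycle cost; 'originator' prices
        ``tablets_per_cycle`` tablets at the originator unit price times
        ``multiplier`` (the knob of the threshold analysis).
        """
        if scenario == "generic":
            return self.drug_cost_per_cycle["sildenafil"] * multiplier
        if scenario == "originator":
            return self.tablets_per_cycle * self.tablet_price["sildenafil_originator"] * multiplier
        raise ValueError(f"unknown price scenario {scenario!r}")


class UtilitySet(BaseModel):
    """EQ-5D utility weight of each functional class (0 dead .. 1 full health)."""

    fc1: MomentSpec
    fc2: MomentSpec
    fc3: MomentSpec
    fc4: MomentSpec

    @model_validator(mode="after")
    def _bounded(self) -> "UtilitySet":
        for k in ("fc1", "fc2", "fc3", "fc4"):
            u = getattr(self, k).mean
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"utility {k} must lie in [0, 1], got {u}")
        return self

    def __getitem__(self, fc: FunctionalClass) -> MomentSpec:
        return getattr(self, fc.key)


class EconSettings(BaseModel):
    annual_discount_rate: float = 0.03
    cycle_length_years: float = 0.25
    horizon_cycles: int = 140
    wtp_per_qaly: float = 3109.0
    perspective: str = "societal"
    half_cycle_correction: bool = False
    idr_per_usd: float = 13830.0

    @model_validator(mode="after")
    def _check(self) -> "EconSettings":
        if self.annual_discount_rate < 0:
            raise ValueError("discount rate must be >= 0")
        if self.horizon_cycles < 1:
            raise ValueError("horizon_cycles must be >= 1")
        if self.perspective not in ("societal", "government"):
            raise ValueError(f"unknown perspective {self.perspective!r}")
        return self


class EpiInputs(BaseModel):
    """Eligible-population inputs for the budget projection."""

    prevalence: float = 8000.0
    annual_incidence: float = 605.0
    fc2_fraction: float = 0.5
    fc3_fraction: float = 0.5
    include_year1_incidence: bool = True

    @model_validator(mode="after")
    def _check(self) -> "EpiInputs":
        if self.prevalence < 0 or self.annual_incidence < 0:
            raise ValueError("prevalence and incidence must be >= 0")
        if abs(self.fc2_fraction + self.fc3_fraction - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        return self


class ParameterSet(BaseModel):
    """Complete, validated model input set."""

    transitions: BaselineTransitions
    deaths: DeathProbabilities
    effects: Dict[str, TreatmentEffect]
    costs: CostComponents
    utilities: UtilitySet
    settings: EconSettings = Field(default_factory=EconSettings)
    epidemiology: EpiInputs = Field(default_factory=EpiInputs)

    @model_validator(mode="after")
    def _drugs_known(self) -> "ParameterSet":
        for drug in self.effects:
            if drug not in DRUGS:
                raise ValueError(f"unknown drug {drug!r} in effects")
        return self


def aggregate_direct_medical_cost(costs: CostComponents, fc: FunctionalClass) -> float:
    """Per-cycle direct medical cost of a class, excluding the selective drug.

    admissions x cost-per-admission + visits x cost-per-visit; the death
    state accrues nothing by contract (no error).
    """
    if fc is FunctionalClass.DEATH:
        return 0.0
    return (
        costs.admissions_per_cycle[fc].mean * costs.cost_per_admission.mean
        + costs.visits_per_cycle[fc].mean * costs.cost_per_visit.mean
    )


class ConfigError(ValueError):
    """Configuration failed validation; message carries JSON-pointer-style paths."""


def _format_validation_error(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        pointer = "/" + "/".join(str(p) for p in err["loc"])
        lines.append(f"{pointer}: {err['msg']}")
    return "invalid parameter configuration:\n" + "\n".join(lines)


def parameter_set_from_dict(doc: dict) -> ParameterSet:
    try:
        return ParameterSet.model_validate(doc)
    except ValidationError as exc:
        raise ConfigError(_format_validation_error(exc)) from exc


def load_parameter_set(path: str | Path) -> ParameterSet:
    """Read and validate a YAML/JSON parameter configuration."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: expected a mapping at the document root")
    return parameter_set_from_dict(doc)


def save_parameter_set(params: ParameterSet, path: str | Path) -> None:
    """Write a configuration that round-trips byte-stably through load."""
    with open(path, "w") as fh:
        yaml.safe_dump(params.model_dump(mode="json"), fh, sort_keys=True)


def default_parameters() -> ParameterSet:
    """The bundled canonical parameterization."""
    ref = importlib.resources.files("pahcea").joinpath("data/table1.yaml")
    return parameter_set_from_dict(yaml.safe_load(ref.read_text()))
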