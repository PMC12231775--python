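"""Parameter types and configuration I/O for the test-and-treat model.

Every model input — diagnostic test accuracies, cohort definition,
anti-amyloid treatment (AAT) specification, disease-progression and
mortality models, costs by payer sector, utilities, and economic
settings — is carried by a validated pydantic model and can be read
from / written to a YAML configuration file.  The bundled base case
lives in ``adcea/data/base_case.yaml``.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Literal, Optional, Union

import pandas as pd
import yaml
from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    ValidationError,
    field_validator,
    model_validator,
)

#: Canonical disease states, ordered by severity; no backward transitions.
STATES = ("MCI", "mild", "moderate", "severe", "dead")
LIVING_STATES = STATES[:-1]
#: Progression tracks: amyloid pathology present (AD) or absent (nonAD).
TRACKS = ("AD", "nonAD")
#: Payer sectors used to split annual state costs.
SECTORS = (
    "municipal_institutional",
    "municipal_home_care",
    "medical_hospital",
    "medical_open_care",
    "medical_drugs_other",
    "informal_care",
)
#: Diagnostic strategies.  SoC = standard of care (no amyloid test, no AAT).
STRATEGY_NAMES = ("SoC", "CSF", "BBM", "BBM_CSF")

#: Retirement age below which annual productivity costs (if configured) accrue.
RETIREMENT_AGE = 65

# Documented currency metadata for the 2019 cost year (not a conversion engine).
CURRENCY_METADATA = {"cost_year": 2019, "EUR_per_SEK": 1 / 10.545,
                     "EUR_per_NOK": 1 / 8.955, "EUR_per_USD": 1 / 1.120}


class ParamError(ValueError):
    """Raised when a configuration fails to parse or violates an invariant."""


def _bayes_ppv(sens: float, spec: float, prevalence: float) -> float:
    pos = sens * prevalence + (1 - spec) * (1 - prevalence)
    return sens * prevalence / pos if pos > 0 else float("nan")


def _bayes_npv(sens: float, spec: float, prevalence: float) -> float:
    neg = spec * (1 - prevalence) + (1 - sens) * prevalence
    return spec * (1 - prevalence) / neg if neg > 0 else float("nan")


class DiagnosticTest(BaseModel):
    """Dichotomous diagnostic test accuracy against a reference standard.

    ``sens`` = P(test+ | condition+), ``spec`` = P(test− | condition−).
    ``ppv``/``npv`` are optional Bayes-derived predictive values at the
    stated ``prevalence`` of the reference condition.
    """

    model_config = ConfigDict(extra="forbid")

    name: str
    sens: float = Field(ge=0.0, le=1.0)
    spec: float = Field(ge=0.0, le=1.0)
    ppv: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    npv: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    prevalence: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    unit_cost: float = Field(default=0.0, ge=0.0)

    @model_validator(mode="after")
    def _predictive_values_consistent(self) -> "DiagnosticTest":
        if self.ppv is not None or self.npv is not None:
            if self.prevalence is None:
                raise ValueError(
                    "ppv/npv given without the prevalence they were derived at")
            if self.ppv is not None:
                expect = _bayes_ppv(self.sens, self.spec, self.prevalence)
                if abs(self.ppv - expect) > 1e-9:
                    raise ValueError(
                        f"ppv {self.ppv} inconsistent with Bayes value "
                        f"{expect:.12f} at prevalence {self.prevalence}")
            if self.npv is not None:
                expect = _bayes_npv(self.sens, self.spec, self.prevalence)
                if abs(self.npv - expect) > 1e-9:
                    raise ValueError(
                        f"npv {self.npv} inconsistent with Bayes value "
                        f"{expect:.12f} at prevalence {self.prevalence}")
        return self


def accuracy_from_counts(tp: int, fp: int, fn: int, tn: int,
                         name: str = "test") -> DiagnosticTest:
    """Build a :class:`DiagnosticTest` from a 2×2 validation table.

    sens = tp/(tp+fn), spec = tn/(tn+fp), ppv = tp/(tp+fp),
    npv = tn/(tn+fn).  Scale-invariant in the counts.

    Raises :class:`ParamError` naming the undefined quantity when a
    margin is zero.
    """
    for label, v in (("tp", tp), ("fp", fp), ("fn", fn), ("tn", tn)):
        if v < 0:
            raise ParamError(f"count {label} must be >= 0, got {v}")
    if tp + fn == 0:
        raise ParamError("sensitivity undefined: tp + fn = 0")
    if tn + fp == 0:
        raise ParamError("specificity undefined: tn + fp = 0")
    total = tp + fp + fn + tn
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ppv = tp / (tp + fp) if tp + fp > 0 else None
    npv = tn / (tn + fn) if tn + fn > 0 else None
    return DiagnosticTest(name=name, sens=sens, spec=spec, ppv=ppv, npv=npv,
                          prevalence=(tp + fn) / total)


def accuracy_from_predictive_values(ppv: float, npv: float, prevalence: float,
                                    name: str = "test") -> DiagnosticTest:
    """Invert quoted PPV/NPV at a known prevalence back to sens/spec.

    With t = P(test+), consistency requires
    prevalence = ppv·t + (1−npv)·(1−t), hence
    t = (prevalence + npv − 1) / (ppv + npv − 1), then
    sens = ppv·t/prevalence and spec = npv·(1−t)/(1−prevalence).
    """
    denom = ppv + npv - 1
    if denom <= 0:
        raise ParamError("ppv + npv must exceed 1 for a non-degenerate test")
    t = (prevalence + npv - 1) / denom
    if not 0 <= t <= 1:
        raise ParamError(
            f"quoted ppv/npv incompatible with prevalence {prevalence}: "
            f"implied positivity rate {t:.4f} outside [0, 1]")
    sens = ppv * t / prevalence
    spec = npv * (1 - t) / (1 - prevalence)
    if not (0 <= sens <= 1 and 0 <= spec <= 1):
        raise ParamError("implied sens/spec outside [0, 1]")
    return DiagnosticTest(name=name, sens=sens, spec=spec, ppv=ppv, npv=npv,
                          prevalence=prevalence)


class CohortSpec(BaseModel):
    """Simulated cohort: size, entry age, amyloid prevalence, start states."""

    model_config = ConfigDict(extra="forbid")

    size: int = Field(default=100_000, gt=0)
    start_age: float = Field(default=70.0, ge=0.0)
    prevalence: float = Field(default=0.4902, ge=0.0, le=1.0)
    start_state_mix: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {"AD": {"MCI": 1.0}, "nonAD": {"MCI": 1.0}})

    @model_validator(mode="after")
    def _mix_valid(self) -> "CohortSpec":
        for track in TRACKS:
            if track not in self.start_state_mix:
                raise ValueError(f"start_state_mix missing track {track!r}")
            mix = self.start_state_mix[track]
            for state in mix:
                if state not in LIVING_STATES:
                    raise ValueError(
                        f"start_state_mix[{track!r}] references unknown "
                        f"state {state!r}")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(
                    f"start_state_mix[{track!r}] must sum to 1")
            if any(v < 0 for v in mix.values()):
                raise ValueError(f"start_state_mix[{track!r}] has negative mass")
        return self


class MonitoringSchedule(BaseModel):
    """Counts of safety-monitoring contacts per treatment year."""

    model_config = ConfigDict(extra="forbid")

    physician_visits: int = Field(ge=0)
    mri: int = Field(ge=0)


class TreatmentSpec(BaseModel):
    """Anti-amyloid treatment: effect, schedule, price, monitoring.

    The base case slows the MCI→mild and mild→moderate conversions by
    30% with no waning and no discontinuation; monitoring is 4 physician
    visits + 4 MRI in year 1 and 1 + 1 every later treatment year.
    """

    model_config = ConfigDict(extra="forbid")

    effect_mci: float = Field(default=0.30, ge=0.0, le=1.0)
    effect_mild: float = Field(default=0.30, ge=0.0, le=1.0)
    effect_moderate: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    waning_rate: float = Field(default=0.0, le=1.0)  # negative = effect growth
    discontinuation_year1: float = Field(default=0.0, ge=0.0, le=1.0)
    drug_price: float = Field(default=5000.0, ge=0.0)
    admin_mode: Literal["infusion", "subcutaneous"] = "infusion"
    admin_unit_cost: float = Field(default=285.0, ge=0.0)
    infusions_per_year: int = Field(default=26, ge=0)
    monitoring_year1: MonitoringSchedule = Field(
        default_factory=lambda: MonitoringSchedule(physician_visits=4, mri=4))
    monitoring_later: MonitoringSchedule = Field(
        default_factory=lambda: MonitoringSchedule(physician_visits=1, mri=1))
    treat_states: tuple[str, ...] = ("MCI", "mild")
    effect_states: tuple[str, ...] = ("MCI", "mild")

    @model_validator(mode="after")
    def _states_valid(self) -> "TreatmentSpec":
        for label, states in (("treat_states", self.treat_states),
                              ("effect_states", self.effect_states)):
            for s in states:
                if s not in LIVING_STATES:
                    raise ValueError(f"{label} references unknown state {s!r}")
        if not set(self.treat_states) >= set(self.effect_states):
            raise ValueError("treat_states must be a superset of effect_states")
        return self

    def effect_for(self, state: str) -> float:
        """Base-year fractional reduction of the progression out of `state`."""
        if state not in self.effect_states:
            return 0.0
        if state == "MCI":
            return self.effect_mci
        if state == "mild":
            return self.effect_mild
        if state == "moderate":
            return self.effect_moderate if self.effect_moderate is not None \
                else self.effect_mild
        return 0.0


class OrderedLogitSpec(BaseModel):
    """Optional cumulative-logit parameterization of annual progression.

    ``cutpoints`` are the strictly increasing thresholds of the latent
    severity scale; ``linear_predictor`` gives the index per track and
    source state.  The derived annual one-step progression probability
    is P(next-year category > source category).
    """

    model_config = ConfigDict(extra="forbid")

    cutpoints: list[float]
    linear_predictor: dict[str, dict[str, float]]

    @field_validator("cutpoints")
    @classmethod
    def _increasing(cls, v: list[float]) -> list[float]:
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("cutpoints must be strictly increasing")
        return v


class TransitionModel(BaseModel):
    """Annual progression probabilities, conditional on survival.

    ``probs[track][state]`` is the annual probability of advancing one
    severity state (MCI→mild, mild→moderate, moderate→severe); severe
    has no further progression, and there are no backward transitions.
    """

    model_config = ConfigDict(extra="forbid")

    probs: dict[str, dict[str, float]]
    ordered_logit: Optional[OrderedLogitSpec] = None

    @model_validator(mode="after")
    def _valid(self) -> "TransitionModel":
        for track in TRACKS:
            if track not in self.probs:
                raise ValueError(f"transition probs missing track {track!r}")
            for state, p in self.probs[track].items():
                if state not in ("MCI", "mild", "moderate"):
                    raise ValueError(
                        f"transition from unknown/terminal state {state!r}")
                if not 0.0 <= p <= 1.0:
                    raise ValueError(
                        f"transition probs[{track!r}][{state!r}] = {p} "
                        "outside [0, 1]")
        return self

    def progression(self, track: str, state: str) -> float:
        return self.probs[track].get(state, 0.0)


class MortalityModel(BaseModel):
    """General-population life table plus per-state mortality hazard ratios.

    MCI carries the general-population risk (HR fixed at 1); dementia
    severity states multiply the general-population hazard.
    """

    model_config = ConfigDict(extra="forbid")

    life_table: dict[int, float]
    hr_by_state: dict[str, float] = Field(
        default_factory=lambda: {"MCI": 1.0, "mild": 1.5,
                                 "moderate": 2.5, "severe": 3.5})

    @model_validator(mode="after")
    def _valid(self) -> "MortalityModel":
        for age, q in self.life_table.items():
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"life_table[{age}] = {q} outside [0, 1]")
        for state, hr in self.hr_by_state.items():
            if state not in LIVING_STATES:
                raise ValueError(f"hr_by_state references unknown state {state!r}")
            if hr < 0:
                raise ValueError(f"hr_by_state[{state!r}] must be >= 0")
        if abs(self.hr_by_state.get("MCI", 1.0) - 1.0) > 1e-12:
            raise ValueError("hr_by_state['MCI'] is fixed at 1.0")
        return self


def life_table_from_csv(path: Union[str, Path]) -> dict[int, float]:
    """Read a two-column life table CSV (age, annual death probability)."""
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    if len(df.columns) < 2:
        raise ParamError(f"life table {path}: expected 2 columns, "
                         f"got {list(df.columns)}")
    df.columns = cols[: len(df.columns)]
    age_col, q_col = df.columns[0], df.columns[1]
    return {int(a): float(q) for a, q in zip(df[age_col], df[q_col])}


def life_table_to_csv(table: dict[int, float], path: Union[str, Path]) -> None:
    pd.DataFrame({"age": sorted(table),
                  "death_prob": [table[a] for a in sorted(table)]}
                 ).to_csv(path, index=False)


class CostSet(BaseModel):
    """Annual state costs by payer sector, diagnostic work-up costs per
    strategy, monitoring unit costs, and the optional productivity cost."""

    model_config = ConfigDict(extra="forbid")

    state_costs: dict[str, dict[str, float]]
    diagnostic_costs: dict[str, float]
    physician_visit_cost: float = Field(default=300.0, ge=0.0)
    mri_cost: float = Field(default=300.0, ge=0.0)
    productivity_cost_annual: Optional[float] = Field(default=None, ge=0.0)

    @model_validator(mode="after")
    def _valid(self) -> "CostSet":
        for state, sectors in self.state_costs.items():
            if state not in LIVING_STATES:
                raise ValueError(f"state_costs references unknown state {state!r}")
            for sector, c in sectors.items():
                if sector not in SECTORS:
                    raise ValueError(
                        f"state_costs[{state!r}] unknown sector {sector!r}")
                if c < 0:
                    raise ValueError(
                        f"state_costs[{state!r}][{sector!r}] must be >= 0")
        for strat, c in self.diagnostic_costs.items():
            if strat not in STRATEGY_NAMES:
                raise ValueError(f"diagnostic_costs unknown strategy {strat!r}")
            if c < 0:
                raise ValueError(f"diagnostic_costs[{strat!r}] must be >= 0")
        return self

    def sector_cost(self, state: str, sector: str) -> float:
        try:
            return self.state_costs[state].get(sector, 0.0)
        except KeyError:
            raise ParamError(f"no state costs configured for state {state!r}")


class UtilitySet(BaseModel):
    """QALY weights per living state (dead is exactly 0) and the optional
    misdiagnosis disutility for false positives / false negatives."""

    model_config = ConfigDict(extra="forbid")

    utilities: dict[str, float]
    misdiagnosis_disutility: float = Field(default=0.0, ge=0.0)
    disutility_duration: Union[Literal["lifetime"], float] = "lifetime"

    @model_validator(mode="after")
    def _valid(self) -> "UtilitySet":
        for state, u in self.utilities.items():
            if state == "dead":
                if u != 0.0:
                    raise ValueError("utilities['dead'] must be exactly 0")
                continue
            if state not in LIVING_STATES:
                raise ValueError(f"utilities references unknown state {state!r}")
            if not -1.0 <= u <= 1.0:
                raise ValueError(f"utilities[{state!r}] = {u} outside [-1, 1]")
        if isinstance(self.disutility_duration, float) and \
                self.disutility_duration < 0:
            raise ValueError("disutility_duration must be >= 0 or 'lifetime'")
        return self

    def utility(self, state: str) -> float:
        if state == "dead":
            return 0.0
        try:
            return self.utilities[state]
        except KeyError:
            raise ParamError(f"no utility configured for state {state!r}")


class EconSettings(BaseModel):
    """Discounting, willingness to pay, and the model horizon."""

    model_config = ConfigDict(extra="forbid")

    discount_rate: float = Field(default=0.03, ge=0.0)
    wtp: float = Field(default=94_800.0, gt=0.0)
    horizon_years: int = Field(default=30, ge=1)
    cycle_length: float = 1.0
    half_cycle: bool = True

    @field_validator("cycle_length")
    @classmethod
    def _annual(cls, v: float) -> float:
        if v != 1.0:
            raise ValueError("cycle_length is fixed at 1 year")
        return v


class ModelParams(BaseModel):
    """Full parameter bundle for one model run."""

    model_config = ConfigDict(extra="forbid")

    cohort: CohortSpec = Field(default_factory=CohortSpec)
    tests: dict[str, DiagnosticTest]
    treatment: TreatmentSpec = Field(default_factory=TreatmentSpec)
    transitions: TransitionModel
    mortality: MortalityModel
    costs: CostSet
    utilities: UtilitySet
    econ: EconSettings = Field(default_factory=EconSettings)
    rng_seed: int = 0

    @model_validator(mode="after")
    def _cross_valid(self) -> "ModelParams":
        for key in ("csf", "bbm"):
            if key not in self.tests:
                raise ValueError(f"tests must include {key!r}")
        for state in LIVING_STATES:
            if state not in self.costs.state_costs:
                raise ValueError(f"state_costs missing state {state!r}")
            if state not in self.utilities.utilities:
                raise ValueError(f"utilities missing state {state!r}")
            if state not in self.mortality.hr_by_state:
                raise ValueError(f"hr_by_state missing state {state!r}")
        first = math.floor(self.cohort.start_age)
        last = math.ceil(self.cohort.start_age + self.econ.horizon_years) - 1
        missing = [a for a in range(first, last + 1)
                   if a not in self.mortality.life_table]
        if missing:
            raise ValueError(
                f"life_table must cover ages {first}..{last}; "
                f"missing {missing[:5]}{'...' if len(missing) > 5 else ''}")
        for strat in STRATEGY_NAMES:
            if strat not in self.costs.diagnostic_costs:
                raise ValueError(f"diagnostic_costs missing strategy {strat!r}")
        return self


# ---------------------------------------------------------------------------
# Configuration I/O

_SECTION_KEYS = ("cohort", "tests", "treatment", "transitions", "mortality",
                 "costs", "utilities", "econ", "rng_seed")


def _format_validation_error(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        path = ".".join(str(p) for p in err["loc"]) or "<root>"
        lines.append(f"{path}: {err['msg']}")
    return "; ".join(lines)


def load_params(path: Union[str, Path]) -> ModelParams:
    """Load and validate a model configuration file.

    The ``mortality`` section may carry the life table inline
    (``life_table: {age: q, ...}``) or reference a two-column CSV via
    ``life_table_csv`` (resolved relative to the config file).
    Missing optional fields are filled with the documented base-case
    defaults.  Raises :class:`ParamError` with the offending field path
    on parse or invariant failure.
    """
    path = Path(path)
    if not path.exists():
        raise ParamError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ParamError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ParamError(f"{path}: top level must be a mapping")
    unknown = set(raw) - set(_SECTION_KEYS)
    if unknown:
        raise ParamError(f"{path}: unknown sections {sorted(unknown)}")
    mortality = raw.get("mortality", {})
    if isinstance(mortality, dict) and "life_table_csv" in mortality:
        mortality = dict(mortality)
        csv_path = Path(mortality.pop("life_table_csv"))
        if not csv_path.is_absolute():
            csv_path = path.parent / csv_path
        mortality["life_table"] = life_table_from_csv(csv_path)
        raw = dict(raw, mortality=mortality)
    try:
        return ModelParams.model_validate(raw)
    except ValidationError as exc:
        raise ParamError(
            f"{path}: {_format_validation_error(exc)}") from exc


def write_params(params: ModelParams, path: Union[str, Path]) -> None:
    """Write a configuration file that :func:`load_params` round-trips."""
    payload = params.model_dump(mode="json", exclude_none=True)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def bundled_config_path(name: str = "base_case") -> Path:
    """Path to a bundled configuration (e.g. ``base_case``)."""
    here = Path(__file__).parent / "data"
    candidate = here / f"{name}.yaml"
    if not candidate.exists():
        available = sorted(p.stem for p in here.glob("*.yaml"))
        raise ParamError(f"no bundled config {name!r}; available: {available}")
    return candidate


def load_base_case() -> ModelParams:
    """The bundled base-case parameter set."""
    return load_params(bundled_config_path("base_case"))
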