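"""Input parameters, their stratification, and scenario resolution.

The model layers ethnic heterogeneity in five steps ("Models 1–5").
Model 1 keeps only cancer incidence ethnic-specific; each subsequent
model switches on one more ethnic-specific parameter block: cancer
excess mortality (Model 2), cancer disability weights (Model 3),
background mortality with its projection decline (Model 4), and the
prevalent-morbidity envelope pYLD (Model 5).  ``resolve_effective_params``
applies one scenario's switch matrix to a stratum, substituting the
reference group's values wherever a switch says "reference".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Literal, Mapping, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .strata import (
    AGE_BANDS,
    CANCER_SEXES,
    CANCERS,
    DEPRIVATION_TERTILES,
    ETHNICITIES,
    MAX_AGE,
    SEXES,
    StratumKey,
    band_index_of_age,
    stratum_grid,
)

PHASES = ("diagnosis", "remission", "preterminal", "terminal", "cured")
#: phases that carry a cancer-specific monthly cost / disability weight
COSTED_PHASES = ("diagnosis", "remission", "preterminal", "terminal")


class BundleLookupError(KeyError):
    """A parameter table is missing a required stratum."""

    def __init__(self, table: str, key) -> None:
        super().__init__(f"table {table!r} has no entry for {key!r}")
        self.table = table
        self.key = key


# ---------------------------------------------------------------------------
# scalar / schedule parameters (validated pydantic models)
# ---------------------------------------------------------------------------


class PhaseSchedule(BaseModel):
    """Disease-phase durations in months for one cancer."""

    model_config = ConfigDict(frozen=True)

    diagnosis_months: int = Field(gt=0)
    preterminal_months: int = Field(gt=0)
    terminal_months: int = Field(gt=0)
    cure_months: int = Field(gt=0)

    @model_validator(mode="after")
    def _cure_after_phases(self) -> "PhaseSchedule":
        total = self.diagnosis_months + self.preterminal_months + self.terminal_months
        if self.cure_months <= total:
            raise ValueError(
                f"cure_months ({self.cure_months}) must exceed the summed phase "
                f"durations ({total})"
            )
        return self


class DisabilityWeightSet(BaseModel):
    """Per-phase disability weights in [0, 1); cured carries weight 0."""

    model_config = ConfigDict(frozen=True)

    diagnosis: float = Field(ge=0, lt=1)
    preterminal: float = Field(ge=0, lt=1)
    terminal: float = Field(ge=0, lt=1)
    remission: float = Field(ge=0, lt=1)

    def weight(self, phase: str) -> float:
        if phase == "cured":
            return 0.0
        return getattr(self, phase)

    @classmethod
    def zero(cls) -> "DisabilityWeightSet":
        return cls(diagnosis=0.0, preterminal=0.0, terminal=0.0, remission=0.0)


class InterventionSpec(BaseModel):
    """The hypothetical treatment: a proportional cut to excess mortality.

    ``effect`` is the fractional reduction of the monthly excess-mortality
    rate; ``direct_monthly_cost`` (NZ$) accrues during the diagnosis and
    treatment phase; costs and benefits are discounted at ``discount_rate``
    per annum.
    """

    model_config = ConfigDict(frozen=True)

    effect: float = Field(default=0.20, ge=0, le=1)
    direct_monthly_cost: float = Field(default=2500.0, ge=0)
    discount_rate: float = Field(default=0.03, ge=0)


ParamSource = Literal["reference_group", "ethnic_specific"]


class ScenarioSpec(BaseModel):
    """Switch matrix for one heterogeneity layer (cancer incidence is
    always ethnic-specific)."""

    model_config = ConfigDict(frozen=True)

    model_id: int = Field(ge=1, le=5)
    excess_mortality_source: ParamSource
    disability_weights_on: bool
    background_mortality_source: ParamSource
    pyld_on: bool


def canonical_scenarios() -> list[ScenarioSpec]:
    """The five standard layering scenarios, Model 1 through Model 5."""
    return [
        ScenarioSpec(
            model_id=1,
            excess_mortality_source="reference_group",
            disability_weights_on=False,
            background_mortality_source="reference_group",
            pyld_on=False,
        ),
        ScenarioSpec(
            model_id=2,
            excess_mortality_source="ethnic_specific",
            disability_weights_on=False,
            background_mortality_source="reference_group",
            pyld_on=False,
        ),
        ScenarioSpec(
            model_id=3,
            excess_mortality_source="ethnic_specific",
            disability_weights_on=True,
            background_mortality_source="reference_group",
            pyld_on=False,
        ),
        ScenarioSpec(
            model_id=4,
            excess_mortality_source="ethnic_specific",
            disability_weights_on=True,
            background_mortality_source="ethnic_specific",
            pyld_on=False,
        ),
        ScenarioSpec(
            model_id=5,
            excess_mortality_source="ethnic_specific",
            disability_weights_on=True,
            background_mortality_source="ethnic_specific",
            pyld_on=True,
        ),
    ]


class DeprivationWeights(BaseModel):
    """Per-ethnicity probability vector over the three deprivation tertiles."""

    model_config = ConfigDict(frozen=True)

    maori: Tuple[float, float, float]
    non_maori: Tuple[float, float, float]

    def vector(self, ethnicity: str) -> Tuple[float, float, float]:
        return getattr(self, ethnicity)


# ---------------------------------------------------------------------------
# stratified tables (dict-backed, CSV round-trippable)
# ---------------------------------------------------------------------------


@dataclass
class RateTable:
    """Events per person-year, indexed by StratumKey.

    ``kind`` distinguishes incidence from excess-mortality semantics.
    """

    kind: str  # "incidence" | "excess_mortality"
    name: str
    values: Dict[StratumKey, float] = field(default_factory=dict)

    def get(self, key: StratumKey) -> float:
        try:
            return self.values[key]
        except KeyError:
            raise BundleLookupError(self.name, key) from None

    def to_frame(self) -> pd.DataFrame:
        rows = [(k.ethnicity, k.sex, k.age_band, k.deprivation, v)
                for k, v in sorted(self.values.items())]
        return pd.DataFrame(
            rows, columns=["ethnicity", "sex", "age_band", "deprivation", "value"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, kind: str, name: str) -> "RateTable":
        values = {
            StratumKey(r.ethnicity, r.sex, r.age_band, r.deprivation): float(r.value)
            for r in df.itertuples()
        }
        return cls(kind=kind, name=name, values=values)


@dataclass
class LifeTable:
    """Single-year all-cause mortality rates with a projected annual decline.

    ``rates[(ethnicity, sex)]`` is an array of annual rates for ages
    0..110.  Rates decline by ``annual_decline[ethnicity]`` per calendar
    year from ``base_year`` until ``decline_horizon_year`` and are frozen
    thereafter.
    """

    rates: Dict[Tuple[str, str], np.ndarray]
    base_year: int = 2006
    annual_decline: Dict[str, float] = field(
        default_factory=lambda: {"maori": 0.0225, "non_maori": 0.0175}
    )
    decline_horizon_year: int = 2026

    def annual_rate(self, age: int, sex: str, ethnicity: str) -> float:
        if age > MAX_AGE:
            raise ValueError(f"age {age} exceeds the life-table maximum {MAX_AGE}")
        try:
            return float(self.rates[(ethnicity, sex)][age])
        except (KeyError, IndexError):
            raise BundleLookupError("life_table", (ethnicity, sex, age)) from None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (eth, sex), arr in sorted(self.rates.items()):
            for age, rate in enumerate(arr):
                rows.append((age, sex, eth, float(rate)))
        return pd.DataFrame(rows, columns=["age", "sex", "ethnicity", "rate"])

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        base_year: int = 2006,
        annual_decline: Mapping[str, float] | None = None,
        decline_horizon_year: int = 2026,
    ) -> "LifeTable":
        rates: Dict[Tuple[str, str], np.ndarray] = {}
        for (eth, sex), grp in df.groupby(["ethnicity", "sex"]):
            arr = np.full(MAX_AGE + 1, np.nan)
            arr[grp["age"].to_numpy()] = grp["rate"].to_numpy()
            rates[(eth, sex)] = arr
        decline = dict(annual_decline) if annual_decline is not None else {
            "maori": 0.0225,
            "non_maori": 0.0175,
        }
        return cls(
            rates=rates,
            base_year=base_year,
            annual_decline=decline,
            decline_horizon_year=decline_horizon_year,
        )


@dataclass
class PyldTable:
    """Prevalent years lived with disability per person-year, the
    background-morbidity envelope, by ethnicity × sex × age band."""

    values: Dict[Tuple[str, str, str], float] = field(default_factory=dict)

    def get(self, ethnicity: str, sex: str, age_band: str) -> float:
        try:
            return self.values[(ethnicity, sex, age_band)]
        except KeyError:
            raise BundleLookupError("pyld", (ethnicity, sex, age_band)) from None

    def by_band(self, ethnicity: str, sex: str) -> np.ndarray:
        """pYLD as an array aligned with AGE_BANDS (ages past the top
        band reuse the top band's value via band clamping)."""
        return np.array([self.get(ethnicity, sex, b) for b in AGE_BANDS])

    def to_frame(self) -> pd.DataFrame:
        rows = [(e, s, b, v) for (e, s, b), v in sorted(self.values.items())]
        return pd.DataFrame(rows, columns=["ethnicity", "sex", "age_band", "value"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PyldTable":
        return cls(
            values={
                (r.ethnicity, r.sex, r.age_band): float(r.value)
                for r in df.itertuples()
            }
        )


@dataclass
class CostTable:
    """Health-system costs (NZ$).

    * ``background_annual[(age_band, sex)]`` — average annual health-system
      cost for the general population.
    * ``last_six_months[(age_band, sex)]`` — total cost of the final six
      months of life for deaths from causes other than the cancer; spread
      uniformly over those months in valuation.
    * ``cancer_monthly[cancer][phase]`` — additional monthly cost by
      disease phase (cured phase carries no cancer cost).
    """

    background_annual: Dict[Tuple[str, str], float]
    last_six_months: Dict[Tuple[str, str], float]
    cancer_monthly: Dict[str, Dict[str, float]]

    def background(self, age_band: str, sex: str) -> float:
        try:
            return self.background_annual[(age_band, sex)]
        except KeyError:
            raise BundleLookupError("costs.background_annual", (age_band, sex)) from None

    def last6(self, age_band: str, sex: str) -> float:
        try:
            return self.last_six_months[(age_band, sex)]
        except KeyError:
            raise BundleLookupError("costs.last_six_months", (age_band, sex)) from None

    def phase_cost(self, cancer: str, phase: str) -> float:
        if phase == "cured":
            return 0.0
        try:
            return self.cancer_monthly[cancer][phase]
        except KeyError:
            raise BundleLookupError("costs.cancer_monthly", (cancer, phase)) from None

    def background_by_band(self, sex: str) -> np.ndarray:
        return np.array([self.background(b, sex) for b in AGE_BANDS])

    def last6_by_band(self, sex: str) -> np.ndarray:
        return np.array([self.last6(b, sex) for b in AGE_BANDS])


@dataclass
class PopulationTable:
    """Census population counts by ethnicity × sex × age band."""

    counts: Dict[Tuple[str, str, str], float] = field(default_factory=dict)

    def get(self, ethnicity: str, sex: str, age_band: str) -> float:
        try:
            return self.counts[(ethnicity, sex, age_band)]
        except KeyError:
            raise BundleLookupError("population", (ethnicity, sex, age_band)) from None

    def band_total(self, ethnicity: str, age_band: str) -> float:
        return sum(self.get(ethnicity, s, age_band) for s in SEXES)

    def to_frame(self) -> pd.DataFrame:
        rows = [(e, s, b, v) for (e, s, b), v in sorted(self.counts.items())]
        return pd.DataFrame(rows, columns=["ethnicity", "sex", "age_band", "count"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PopulationTable":
        return cls(
            counts={
                (r.ethnicity, r.sex, r.age_band): float(r.count)
                for r in df.itertuples()
            }
        )


# ---------------------------------------------------------------------------
# the full bundle
# ---------------------------------------------------------------------------


@dataclass
class ParameterBundle:
    """Everything the model needs, for all cancers and strata."""

    incidence: Dict[str, RateTable]
    excess_mortality: Dict[str, RateTable]
    life_table: LifeTable
    pyld: PyldTable
    phase_schedules: Dict[str, PhaseSchedule]
    disability_weights: Dict[str, DisabilityWeightSet]
    costs: CostTable
    intervention: InterventionSpec
    deprivation_weights: DeprivationWeights
    population: PopulationTable
    entry_year: int = 2006


@dataclass(frozen=True)
class EffectiveParams:
    """Per-stratum parameters after applying one scenario's switches.

    Reference-group switches have already substituted the reference
    ethnicity's rates; off switches have zeroed the disability weights
    or the pYLD envelope.  ``background_ethnicity`` names the life-table
    column (and hence projection decline) the engine must use.
    """

    cancer: str
    stratum: StratumKey
    incidence_rate: float
    excess_annual_rate: float
    background_ethnicity: str
    schedule: PhaseSchedule
    dw: DisabilityWeightSet
    pyld_by_band: np.ndarray


def resolve_effective_params(
    scenario: ScenarioSpec,
    bundle: ParameterBundle,
    cancer: str,
    stratum: StratumKey,
    reference_ethnicity: str = "non_maori",
) -> EffectiveParams:
    """Apply a scenario's switch matrix to one stratum.

    For any switch set to ``reference_group``, the stratum's rate is taken
    from the matching reference-ethnicity stratum (same sex, age band and
    deprivation); for background mortality this substitutes the reference
    group's life-table column, which carries that group's projection
    decline as well.  Disability weights and pYLD are zeroed when off.
    The reference ethnicity's own strata are unaffected by every switch.
    """
    stratum = StratumKey(*stratum).validate()
    ref_key = stratum._replace(ethnicity=reference_ethnicity)

    incidence = bundle.incidence[cancer].get(stratum)

    if scenario.excess_mortality_source == "reference_group":
        excess = bundle.excess_mortality[cancer].get(ref_key)
    else:
        excess = bundle.excess_mortality[cancer].get(stratum)

    if scenario.background_mortality_source == "reference_group":
        background_ethnicity = reference_ethnicity
    else:
        background_ethnicity = stratum.ethnicity
    if (background_ethnicity, stratum.sex) not in bundle.life_table.rates:
        raise BundleLookupError("life_table", (background_ethnicity, stratum.sex))

    if scenario.disability_weights_on:
        dw = bundle.disability_weights[cancer]
    else:
        dw = DisabilityWeightSet.zero()

    if scenario.pyld_on:
        pyld = bundle.pyld.by_band(stratum.ethnicity, stratum.sex)
    else:
        pyld = np.zeros(len(AGE_BANDS))

    return EffectiveParams(
        cancer=cancer,
        stratum=stratum,
        incidence_rate=incidence,
        excess_annual_rate=excess,
        background_ethnicity=background_ethnicity,
        schedule=bundle.phase_schedules[cancer],
        dw=dw,
        pyld_by_band=pyld,
    )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, msg: str) -> None:
        self.violations.append(msg)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.ok:
            return "bundle OK"
        return "bundle violations:\n" + "\n".join(f"  - {v}" for v in self.violations)


def validate_bundle(bundle: ParameterBundle) -> ValidationReport:
    """Check grid completeness, value ranges and probability-vector sums.

    Returns a report; never raises and never mutates the bundle.
    """
    rep = ValidationReport()

    for cancer in CANCERS:
        for attr, tables in (
            ("incidence", bundle.incidence),
            ("excess_mortality", bundle.excess_mortality),
        ):
            table = tables.get(cancer)
            if table is None:
                rep.add(f"{attr}: missing table for cancer {cancer!r}")
                continue
            for key in stratum_grid(cancer):
                if key not in table.values:
                    rep.add(f"{attr}[{cancer}]: missing stratum {key}")
            for key, v in table.values.items():
                if not np.isfinite(v) or v < 0:
                    rep.add(f"{attr}[{cancer}]: rate {v} out of range at {key}")

    for eth in ETHNICITIES:
        for sex in SEXES:
            arr = bundle.life_table.rates.get((eth, sex))
            if arr is None or len(arr) != MAX_AGE + 1 or np.isnan(arr).any():
                rep.add(f"life_table: incomplete ages for ({eth}, {sex})")
            elif (arr < 0).any():
                rep.add(f"life_table: negative rate for ({eth}, {sex})")
        decline = bundle.life_table.annual_decline.get(eth)
        if decline is None or not 0 <= decline <= 0.04:
            rep.add(f"life_table: annual decline {decline} for {eth} outside [0, 0.04]")

    for eth in ETHNICITIES:
        for sex in SEXES:
            for band in AGE_BANDS:
                v = bundle.pyld.values.get((eth, sex, band))
                if v is None:
                    rep.add(f"pyld: missing ({eth}, {sex}, {band})")
                elif not 0 <= v < 1:
                    rep.add(f"pyld: value {v} outside [0, 1) at ({eth}, {sex}, {band})")

    for cancer in CANCERS:
        dw = bundle.disability_weights.get(cancer)
        if dw is None:
            rep.add(f"disability_weights: missing set for {cancer}")
            continue
        for phase in COSTED_PHASES:
            w = dw.weight(phase)
            if not 0 <= w < 1:
                rep.add(
                    f"disability_weights[{cancer}]: weight {w} for phase "
                    f"{phase!r} outside [0, 1)"
                )
        if cancer not in bundle.phase_schedules:
            rep.add(f"phase_schedules: missing schedule for {cancer}")

    for (band, sex), v in bundle.costs.background_annual.items():
        if v < 0:
            rep.add(f"costs.background_annual: negative cost at ({band}, {sex})")
    for (band, sex), v in bundle.costs.last_six_months.items():
        if v < 0:
            rep.add(f"costs.last_six_months: negative cost at ({band}, {sex})")
    for sex in SEXES:
        for band in AGE_BANDS:
            if (band, sex) not in bundle.costs.background_annual:
                rep.add(f"costs.background_annual: missing ({band}, {sex})")
            if (band, sex) not in bundle.costs.last_six_months:
                rep.add(f"costs.last_six_months: missing ({band}, {sex})")
    for cancer in CANCERS:
        phases = bundle.costs.cancer_monthly.get(cancer, {})
        for phase in COSTED_PHASES:
            v = phases.get(phase)
            if v is None:
                rep.add(f"costs.cancer_monthly[{cancer}]: missing phase {phase!r}")
            elif v < 0:
                rep.add(f"costs.cancer_monthly[{cancer}]: negative cost for {phase!r}")

    for eth in ETHNICITIES:
        vec = bundle.deprivation_weights.vector(eth)
        if abs(sum(vec) - 1.0) > 1e-9:
            rep.add(
                f"deprivation_weights[{eth}]: vector sums to {sum(vec):.6f}, not 1"
            )
        if any(w < 0 for w in vec):
            rep.add(f"deprivation_weights[{eth}]: negative weight")

    for eth in ETHNICITIES:
        for sex in SEXES:
            for band in AGE_BANDS:
                c = bundle.population.counts.get((eth, sex, band))
                if c is None:
                    rep.add(f"population: missing ({eth}, {sex}, {band})")
                elif c <= 0:
                    rep.add(f"population: non-positive count at ({eth}, {sex}, {band})")

    return rep


# ---------------------------------------------------------------------------
# standard phase schedules and disability weights for the three cancers
# ---------------------------------------------------------------------------


def reference_phase_schedules() -> Dict[str, PhaseSchedule]:
    """Phase durations (months) for lung, female breast and colon cancer:
    diagnosis/treatment, pre-terminal, terminal, and statistical cure time."""
    return {
        "lung": PhaseSchedule(
            diagnosis_months=5, preterminal_months=5, terminal_months=1, cure_months=72
        ),
        "breast": PhaseSchedule(
            diagnosis_months=6, preterminal_months=11, terminal_months=1,
            cure_months=240,
        ),
        "colon": PhaseSchedule(
            diagnosis_months=9, preterminal_months=3, terminal_months=1, cure_months=96
        ),
    }


def reference_disability_weights() -> Dict[str, DisabilityWeightSet]:
    """Per-phase disability weights for the three cancers."""
    return {
        "lung": DisabilityWeightSet(
            diagnosis=0.469, preterminal=0.539, terminal=0.548, remission=0.315
        ),
        "breast": DisabilityWeightSet(
            diagnosis=0.194, preterminal=0.512, terminal=0.520, remission=0.174
        ),
        "colon": DisabilityWeightSet(
            diagnosis=0.288, preterminal=0.539, terminal=0.548, remission=0.167
        ),
    }
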