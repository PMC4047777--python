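"""Seeded synthetic parameter bundles with NZ-like structure.

No deposited input tables exist for this model, so this module generates
parameter bundles that reproduce the *structure* of the real inputs:

* Māori lung-cancer incidence about 3× non-Māori, breast +17%, colon −40%;
* Māori excess (cancer) mortality higher for all three cancers, with the
  three cancers in different absolute-survival regimes (lung low
  survival, breast and colon high);
* Māori background mortality higher at every age, projected with a
  faster annual decline (2.25%/yr vs 1.75%/yr up to 2026);
* Māori prevalent background morbidity (pYLD) higher at every age;
* the Māori population skewed toward the most deprived tertile.

Ethnic rate ratios are applied as exact multiplicative factors on top of
stratum-level noise that is shared between ethnicities, so the embedded
ratios hold exactly in every stratum while bundles still vary by seed.
All values are synthetic and calibrated to nothing; they exist to make
every stage of the model testable.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .params import (
    CostTable,
    DeprivationWeights,
    InterventionSpec,
    LifeTable,
    ParameterBundle,
    PopulationTable,
    PyldTable,
    RateTable,
    reference_disability_weights,
    reference_phase_schedules,
)
from .strata import (
    AGE_BANDS,
    CANCER_SEXES,
    CANCERS,
    DEPRIVATION_TERTILES,
    ETHNICITIES,
    MAX_AGE,
    SEXES,
    StratumKey,
    band_midpoint,
)


class SyntheticConfig(BaseModel):
    """Knobs of the synthetic-bundle generator (all rates per person-year)."""

    model_config = ConfigDict(frozen=True)

    # Māori / non-Māori incidence rate ratios
    incidence_ratio: Dict[str, float] = Field(
        default_factory=lambda: {"lung": 3.0, "breast": 1.17, "colon": 0.6}
    )
    #: non-Māori incidence at ages 65-69, middle deprivation
    incidence_base: Dict[str, float] = Field(
        default_factory=lambda: {"lung": 0.002, "breast": 0.003, "colon": 0.0025}
    )
    incidence_age_slope: Dict[str, float] = Field(
        default_factory=lambda: {"lung": 0.05, "breast": 0.01, "colon": 0.045}
    )
    # Māori / non-Māori excess-mortality rate ratios (all > 1)
    excess_ratio: Dict[str, float] = Field(
        default_factory=lambda: {"lung": 1.35, "breast": 1.5, "colon": 1.35}
    )
    #: non-Māori annual excess-mortality rate; lung sits in a low
    #: absolute-survival regime, breast and colon in high-survival regimes
    excess_base: Dict[str, float] = Field(
        default_factory=lambda: {"lung": 0.45, "breast": 0.045, "colon": 0.09}
    )
    excess_age_slope: float = 0.012
    #: deprivation gradients (multipliers for dep1_3 / dep4_6 / dep7_10)
    incidence_dep_gradient: Tuple[float, float, float] = (0.8, 1.0, 1.25)
    excess_dep_gradient: Tuple[float, float, float] = (0.9, 1.0, 1.15)
    # background mortality (Gompertz-like: rate(70) × exp(slope × (age−70)))
    background_rate_at_70: float = 0.02
    background_age_slope: float = 0.09
    background_female_factor: float = 0.65
    background_ethnic_ratio: float = 1.7
    annual_decline: Dict[str, float] = Field(
        default_factory=lambda: {"maori": 0.0225, "non_maori": 0.0175}
    )
    base_year: int = 2006
    decline_horizon_year: int = 2026
    # background morbidity envelope
    pyld_at_70_74: float = 0.224
    pyld_age_slope: float = 0.006  # per year of band-midpoint age
    pyld_male_factor: float = 0.9
    pyld_maori_uplift: float = 0.06  # additive, every age
    # deprivation distributions (dep1_3, dep4_6, dep7_10)
    deprivation_maori: Tuple[float, float, float] = (0.15, 0.25, 0.60)
    deprivation_non_maori: Tuple[float, float, float] = (0.40, 0.35, 0.25)
    # populations at the youngest band, declining with age
    population_base: Dict[str, float] = Field(
        default_factory=lambda: {"maori": 15000.0, "non_maori": 120000.0}
    )
    population_age_slope: Dict[str, float] = Field(
        default_factory=lambda: {"maori": -0.06, "non_maori": -0.035}
    )
    # costs (NZ$)
    background_cost_at_45_49: float = 1200.0
    background_cost_age_slope: float = 0.035
    last_six_months_cost: float = 25000.0
    #: multiplicative lognormal noise (sigma of log) on incidence / excess
    noise_sd: float = 0.05

    def check_feasible(self) -> None:
        for name, table in (
            ("incidence_ratio", self.incidence_ratio),
            ("incidence_base", self.incidence_base),
            ("excess_ratio", self.excess_ratio),
            ("excess_base", self.excess_base),
        ):
            for cancer in CANCERS:
                v = table.get(cancer)
                if v is None or v <= 0 or not np.isfinite(v):
                    raise ValueError(
                        f"infeasible config: {name}[{cancer!r}] = {v!r} "
                        "(must be a positive finite number)"
                    )
        if not 0 <= self.pyld_maori_uplift < 1:
            raise ValueError("infeasible config: pyld_maori_uplift outside [0, 1)")
        for eth, vec in (
            ("maori", self.deprivation_maori),
            ("non_maori", self.deprivation_non_maori),
        ):
            if any(w < 0 for w in vec) or abs(sum(vec) - 1) > 1e-9:
                raise ValueError(
                    f"infeasible config: deprivation_{eth} is not a probability vector"
                )


_ETHNICITY_SEED = {"maori": 0, "non_maori": 0}  # noise shared across ethnicity
_SEX_FACTOR_INCIDENCE = {"lung": {"female": 1.0, "male": 1.3},
                         "breast": {"female": 1.0},
                         "colon": {"female": 1.0, "male": 1.2}}


def generate_population(
    seed: int, config: SyntheticConfig | None = None
) -> tuple[PopulationTable, DeprivationWeights]:
    """Ethnic population counts by sex × age band plus deprivation
    distributions (Māori skewed toward the most deprived tertile)."""
    config = config or SyntheticConfig()
    config.check_feasible()
    rng = np.random.default_rng(seed)
    counts: Dict[Tuple[str, str, str], float] = {}
    for eth in ETHNICITIES:
        base = config.population_base[eth]
        slope = config.population_age_slope[eth]
        for sex in SEXES:
            for band in AGE_BANDS:
                mid = band_midpoint(band)
                noise = np.exp(rng.normal(0.0, 0.02))
                counts[(eth, sex, band)] = float(
                    np.round(base / 2.0 * np.exp(slope * (mid - 47.5)) * noise)
                )
    weights = DeprivationWeights(
        maori=config.deprivation_maori, non_maori=config.deprivation_non_maori
    )
    return PopulationTable(counts=counts), weights


def _rate_tables(
    rng: np.random.Generator, config: SyntheticConfig
) -> tuple[Dict[str, RateTable], Dict[str, RateTable]]:
    incidence: Dict[str, RateTable] = {}
    excess: Dict[str, RateTable] = {}
    for cancer in CANCERS:
        inc_values: Dict[StratumKey, float] = {}
        exc_values: Dict[StratumKey, float] = {}
        for sex in CANCER_SEXES[cancer]:
            for band in AGE_BANDS:
                mid = band_midpoint(band)
                for i, dep in enumerate(DEPRIVATION_TERTILES):
                    # noise shared across ethnicities so ratios are exact
                    inc_noise = np.exp(rng.normal(0.0, config.noise_sd))
                    exc_noise = np.exp(rng.normal(0.0, config.noise_sd))
                    inc_nm = (
                        config.incidence_base[cancer]
                        * np.exp(config.incidence_age_slope[cancer] * (mid - 67.5))
                        * _SEX_FACTOR_INCIDENCE[cancer][sex]
                        * config.incidence_dep_gradient[i]
                        * inc_noise
                    )
                    exc_nm = (
                        config.excess_base[cancer]
                        * np.exp(config.excess_age_slope * (mid - 67.5))
                        * config.excess_dep_gradient[i]
                        * exc_noise
                    )
                    for eth in ETHNICITIES:
                        inc_r = config.incidence_ratio[cancer] if eth == "maori" else 1.0
                        exc_r = config.excess_ratio[cancer] if eth == "maori" else 1.0
                        key = StratumKey(eth, sex, band, dep)
                        inc_values[key] = float(inc_nm * inc_r)
                        exc_values[key] = float(exc_nm * exc_r)
        incidence[cancer] = RateTable(
            kind="incidence", name=f"incidence[{cancer}]", values=inc_values
        )
        excess[cancer] = RateTable(
            kind="excess_mortality",
            name=f"excess_mortality[{cancer}]",
            values=exc_values,
        )
    return incidence, excess


def _life_table(config: SyntheticConfig) -> LifeTable:
    ages = np.arange(MAX_AGE + 1)
    male_nm = config.background_rate_at_70 * np.exp(
        config.background_age_slope * (ages - 70)
    )
    rates = {}
    for eth in ETHNICITIES:
        ratio = config.background_ethnic_ratio if eth == "maori" else 1.0
        rates[(eth, "male")] = male_nm * ratio
        rates[(eth, "female")] = male_nm * config.background_female_factor * ratio
    return LifeTable(
        rates=rates,
        base_year=config.base_year,
        annual_decline=dict(config.annual_decline),
        decline_horizon_year=config.decline_horizon_year,
    )


def _pyld_table(config: SyntheticConfig) -> PyldTable:
    values: Dict[Tuple[str, str, str], float] = {}
    for band in AGE_BANDS:
        mid = band_midpoint(band)
        female_nm = config.pyld_at_70_74 + config.pyld_age_slope * (mid - 72.5)
        for sex in SEXES:
            base = female_nm * (config.pyld_male_factor if sex == "male" else 1.0)
            for eth in ETHNICITIES:
                uplift = config.pyld_maori_uplift if eth == "maori" else 0.0
                values[(eth, sex, band)] = float(np.clip(base + uplift, 0.0, 0.95))
    return PyldTable(values=values)


def _cost_table(config: SyntheticConfig) -> CostTable:
    background = {}
    last6 = {}
    for band in AGE_BANDS:
        mid = band_midpoint(band)
        cost = config.background_cost_at_45_49 * np.exp(
            config.background_cost_age_slope * (mid - 47.5)
        )
        for sex in SEXES:
            background[(band, sex)] = float(np.round(cost, 2))
            last6[(band, sex)] = float(config.last_six_months_cost)
    cancer_monthly = {
        "lung": {"diagnosis": 6000.0, "remission": 250.0,
                 "preterminal": 4000.0, "terminal": 9000.0},
        "breast": {"diagnosis": 5000.0, "remission": 200.0,
                   "preterminal": 3500.0, "terminal": 8500.0},
        "colon": {"diagnosis": 5500.0, "remission": 220.0,
                  "preterminal": 3800.0, "terminal": 8800.0},
    }
    return CostTable(
        background_annual=background,
        last_six_months=last6,
        cancer_monthly=cancer_monthly,
    )


def generate_bundle(
    seed: int, config: SyntheticConfig | None = None
) -> ParameterBundle:
    """Generate a complete, validated parameter bundle.

    Deterministic given ``seed``; the embedded ethnic rate ratios hold
    exactly in every stratum and the standard phase schedules and
    disability weights for the three cancers are emitted as defaults.
    """
    config = config or SyntheticConfig()
    config.check_feasible()
    rng = np.random.default_rng(seed)
    incidence, excess = _rate_tables(rng, config)
    population, dep_weights = generate_population(seed + 1, config)
    return ParameterBundle(
        incidence=incidence,
        excess_mortality=excess,
        life_table=_life_table(config),
        pyld=_pyld_table(config),
        phase_schedules=reference_phase_schedules(),
        disability_weights=reference_disability_weights(),
        costs=_cost_table(config),
        intervention=InterventionSpec(),
        deprivation_weights=dep_weights,
        population=population,
        entry_year=config.base_year,
    )
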