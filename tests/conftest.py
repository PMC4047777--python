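import numpy as np
import pytest

from equicea import StratumKey, generate_bundle
from equicea.params import (
    DisabilityWeightSet,
    EffectiveParams,
    LifeTable,
    PhaseSchedule,
)
from equicea.strata import AGE_BANDS, ETHNICITIES, SEXES


@pytest.fixture(scope="session")
def bundle():
    return generate_bundle(1)


@pytest.fixture(scope="session")
def lung_schedule():
    return PhaseSchedule(
        diagnosis_months=5, preterminal_months=5, terminal_months=1, cure_months=72
    )


def flat_life_table(annual_rate: float, decline: float = 0.0) -> LifeTable:
    """Life table with one constant annual rate at every age, for closed-form
    engine checks."""
    rates = {
        (eth, sex): np.full(111, annual_rate) for eth in ETHNICITIES for sex in SEXES
    }
    return LifeTable(
        rates=rates,
        base_year=2006,
        annual_decline={"maori": decline, "non_maori": decline},
        decline_horizon_year=2026,
    )


def make_effective(
    excess_annual_rate: float,
    schedule: PhaseSchedule | None = None,
    dw: DisabilityWeightSet | None = None,
    pyld: np.ndarray | None = None,
    age_band: str = "65-69",
    sex: str = "male",
    ethnicity: str = "non_maori",
) -> EffectiveParams:
    return EffectiveParams(
        cancer="lung",
        stratum=StratumKey(ethnicity, sex, age_band, "dep4_6"),
        incidence_rate=0.001,
        excess_annual_rate=excess_annual_rate,
        background_ethnicity=ethnicity,
        schedule=schedule
        or PhaseSchedule(
            diagnosis_months=5, preterminal_months=5, terminal_months=1,
            cure_months=72,
        ),
        dw=dw or DisabilityWeightSet.zero(),
        pyld_by_band=pyld if pyld is not None else np.zeros(len(AGE_BANDS)),
    )
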