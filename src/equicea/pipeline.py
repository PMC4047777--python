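"""Cost-effectiveness pipeline: expected values, aggregation, reporting.

Combines the Markov engine's absorption distribution with the
trajectory valuation into expected discounted HALYs and costs per case,
aggregates socio-demographic strata with case weights, and derives the
reporting quantities: incremental HALYs and costs, percentage change
against the base scenario, HALY gains per 100,000 ethnic-specific
population, Māori/non-Māori relative risks, and ICERs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .engine import AbsorptionDistribution, run_cohort
from .params import (
    CostTable,
    DisabilityWeightSet,
    InterventionSpec,
    ParameterBundle,
    PhaseSchedule,
    ScenarioSpec,
    canonical_scenarios,
    resolve_effective_params,
)
from .strata import (
    CANCER_SEXES,
    CANCERS,
    DEPRIVATION_TERTILES,
    ETHNICITIES,
    StratumKey,
    band_index_of_age,
    band_midpoint,
)
from .trajectory import discount_factor

#: age bands used for headline reporting
DEFAULT_REPORT_BANDS = ("50-54", "65-69", "80-84")


# ---------------------------------------------------------------------------
# vectorised valuation of every absorbing (cause, month) outcome
# ---------------------------------------------------------------------------


@dataclass
class OutcomeValuation:
    """Discounted HALYs and costs for every absorbing outcome.

    Index ``d-1`` holds the value of the trajectory ending in death at
    month d; survivor values are scalars.  Computed with prefix sums so
    a full horizon's worth of retrospective trajectories is valued in
    one pass; agrees with the per-trajectory routines in
    :mod:`equicea.trajectory` to floating-point accuracy.
    """

    haly_cancer_death: np.ndarray
    haly_other_death: np.ndarray
    cost_cancer_death: np.ndarray
    cost_other_death: np.ndarray
    haly_survivor: float
    cost_survivor: float

    @property
    def n_months(self) -> int:
        return len(self.haly_cancer_death)


def value_all_outcomes(
    schedule: PhaseSchedule,
    dw_set: DisabilityWeightSet,
    pyld_by_band: np.ndarray,
    cost_table: CostTable,
    cancer: str,
    sex: str,
    start_age: float,
    n_months: int,
    discount_rate: float = 0.03,
    direct_monthly_cost: float = 0.0,
    intervention_on: bool = False,
    other_death_terminal_dw: bool = True,
) -> OutcomeValuation:
    """Value the retrospective trajectory of every outcome at once.

    Pass an already-resolved parameter set: a zeroed ``dw_set`` /
    ``pyld_by_band`` encodes switched-off disability weights or
    morbidity envelope.
    """
    T = n_months
    m = np.arange(1, T + 1)
    disc = discount_factor(m, discount_rate)
    band_idx = band_index_of_age(start_age + (m - 1) / 12.0)
    pyld = pyld_by_band[band_idx]

    def prefix(x: np.ndarray) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(x)])

    b = (1.0 - pyld) * disc / 12.0  # HALY value of a healthy (pre-DW) month
    B = prefix(b)
    D = prefix(disc)
    G = prefix(cost_table.background_by_band(sex)[band_idx] / 12.0 * disc)
    L6 = prefix(cost_table.last6_by_band(sex)[band_idx] / 6.0 * disc)

    direct = direct_monthly_cost if intervention_on else 0.0
    c_diag = cost_table.phase_cost(cancer, "diagnosis") + direct
    c_rem = cost_table.phase_cost(cancer, "remission")
    c_pre = cost_table.phase_cost(cancer, "preterminal")
    c_term = cost_table.phase_cost(cancer, "terminal")

    # cancer deaths: end-anchored terminal / pre-terminal, truncated diagnosis
    d = m
    n_term = np.minimum(schedule.terminal_months, d)
    n_pre = np.minimum(schedule.preterminal_months, d - n_term)
    rem_end = d - n_term - n_pre
    n_diag = np.minimum(schedule.diagnosis_months, rem_end)
    haly_cancer = (
        (1.0 - dw_set.diagnosis) * B[n_diag]
        + (1.0 - dw_set.remission) * (B[rem_end] - B[n_diag])
        + (1.0 - dw_set.preterminal) * (B[d - n_term] - B[rem_end])
        + (1.0 - dw_set.terminal) * (B[d] - B[d - n_term])
    )
    cost_cancer = (
        c_diag * D[n_diag]
        + c_rem * (D[rem_end] - D[n_diag])
        + c_pre * (D[d - n_term] - D[rem_end])
        + c_term * (D[d] - D[d - n_term])
        + G[d]
    )

    # survivor schedule (also the truncated other-cause-death schedule)
    in_diag = m <= schedule.diagnosis_months
    in_rem = ~in_diag & (m <= schedule.cure_months)
    sur_dw = np.where(in_diag, dw_set.diagnosis, np.where(in_rem, dw_set.remission, 0.0))
    WS = prefix((1.0 - sur_dw) * b)
    CS = prefix(np.where(in_diag, c_diag, np.where(in_rem, c_rem, 0.0)) * disc)

    if other_death_terminal_dw:
        haly_other = WS[d] + (sur_dw - dw_set.terminal) * b
    else:
        haly_other = WS[d].copy()
    a = np.maximum(d - 6, 0)
    cost_other = CS[d] + G[a] + (L6[d] - L6[a])

    return OutcomeValuation(
        haly_cancer_death=haly_cancer,
        haly_other_death=haly_other,
        cost_cancer_death=cost_cancer,
        cost_other_death=cost_other,
        haly_survivor=float(WS[T]),
        cost_survivor=float(CS[T] + G[T]),
    )


def expected_value(
    absorption: AbsorptionDistribution, valuation: OutcomeValuation
) -> tuple[float, float]:
    """Probability-weighted expected (HALYs, cost) over all outcomes."""
    if valuation.n_months != absorption.n_months:
        raise ValueError(
            f"valuation covers {valuation.n_months} months but the absorption "
            f"distribution has {absorption.n_months}"
        )
    e_haly = float(
        absorption.p_cancer_death @ valuation.haly_cancer_death
        + absorption.p_other_death @ valuation.haly_other_death
        + absorption.p_alive * valuation.haly_survivor
    )
    e_cost = float(
        absorption.p_cancer_death @ valuation.cost_cancer_death
        + absorption.p_other_death @ valuation.cost_other_death
        + absorption.p_alive * valuation.cost_survivor
    )
    return e_haly, e_cost


# ---------------------------------------------------------------------------
# aggregation and derived reporting quantities
# ---------------------------------------------------------------------------


def aggregate_deprivation(
    values: Mapping[str, float],
    dep_weights: Sequence[float],
    incidence_by_dep: Mapping[str, float],
) -> float:
    """Case-weighted mean over deprivation tertiles.

    Weights are the population share of each tertile times its incidence
    rate (i.e. the share of cases arising in the tertile), so a group
    skewed toward deprived tertiles reflects deprived-stratum parameters.
    """
    w = np.array(
        [dep_weights[i] * incidence_by_dep[d] for i, d in enumerate(DEPRIVATION_TERTILES)]
    )
    v = np.array([values[d] for d in DEPRIVATION_TERTILES])
    if w.sum() == 0:
        w = np.asarray(dep_weights, dtype=float)
    return float((w * v).sum() / w.sum())


def per_100k(per_case: float, cases: float, population: float) -> float:
    """Total gain per 100,000 population: per-case × cases ÷ population × 1e5."""
    if population <= 0:
        raise ValueError("population must be positive")
    return per_case * cases / population * 1e5


def pct_change(value: float, reference: float) -> float:
    """Percent change against a reference; NaN when the reference is zero."""
    if reference == 0:
        return float("nan")
    return (value - reference) / reference * 100.0


def rr(maori_value: float, non_maori_value: float) -> float:
    """Māori / non-Māori ratio; NaN when the denominator is zero."""
    if non_maori_value == 0:
        return float("nan")
    return maori_value / non_maori_value


class ICER(NamedTuple):
    value: float
    flag: str  # "ok" | "dominant" | "undefined"


def compute_icer(incremental_cost: float, incremental_haly: float) -> ICER:
    """Net change in costs divided by net health gain.

    Negative cost with positive gain is flagged dominant (the ratio is
    still reported, negative); non-positive health gain is undefined.
    """
    if incremental_haly <= 0:
        return ICER(float("nan"), "undefined")
    value = incremental_cost / incremental_haly
    flag = "dominant" if incremental_cost < 0 else "ok"
    return ICER(value, flag)


# ---------------------------------------------------------------------------
# per-cell evaluation and the full model grid
# ---------------------------------------------------------------------------


def run_cell(
    bundle: ParameterBundle,
    cancer: str,
    scenario: ScenarioSpec,
    stratum: StratumKey,
    intervention_on: bool,
    reference_ethnicity: str = "non_maori",
    intervention: InterventionSpec | None = None,
) -> tuple[float, float]:
    """Expected discounted (HALYs, cost) per case for one stratum/arm."""
    iv = intervention if intervention is not None else bundle.intervention
    eff = resolve_effective_params(scenario, bundle, cancer, stratum, reference_ethnicity)
    absorption = run_cohort(
        eff,
        bundle.life_table,
        entry_year=bundle.entry_year,
        intervention=iv,
        intervention_on=intervention_on,
    )
    valuation = value_all_outcomes(
        eff.schedule,
        eff.dw,
        eff.pyld_by_band,
        bundle.costs,
        cancer,
        stratum.sex,
        absorption.start_age,
        absorption.n_months,
        discount_rate=iv.discount_rate,
        direct_monthly_cost=iv.direct_monthly_cost,
        intervention_on=intervention_on,
    )
    return expected_value(absorption, valuation)


def _cell_summary(
    bundle: ParameterBundle,
    cancer: str,
    scenario: ScenarioSpec,
    ethnicity: str,
    age_band: str,
    reference_ethnicity: str,
    intervention: InterventionSpec | None = None,
) -> dict:
    """Case-weighted (over sex × deprivation) per-case values for one
    cancer × scenario × ethnicity × age-band cell, both arms."""
    iv = intervention if intervention is not None else bundle.intervention
    dep_w = bundle.deprivation_weights.vector(ethnicity)
    sexes = CANCER_SEXES[cancer]

    total_w = 0.0
    acc = {"h0": 0.0, "h1": 0.0, "c0": 0.0, "c1": 0.0}
    pop_at_risk = 0.0
    for sex in sexes:
        pop = bundle.population.get(ethnicity, sex, age_band)
        pop_at_risk += pop
        for i, dep in enumerate(DEPRIVATION_TERTILES):
            key = StratumKey(ethnicity, sex, age_band, dep)
            inc = bundle.incidence[cancer].get(key)
            w = pop * dep_w[i] * inc  # expected annual incident cases
            if w == 0:
                continue
            h0, c0 = run_cell(
                bundle, cancer, scenario, key, False, reference_ethnicity, iv
            )
            h1, c1 = run_cell(
                bundle, cancer, scenario, key, True, reference_ethnicity, iv
            )
            total_w += w
            acc["h0"] += w * h0
            acc["h1"] += w * h1
            acc["c0"] += w * c0
            acc["c1"] += w * c1
    if total_w == 0:
        raise ValueError(
            f"no incident cases for {cancer} / {ethnicity} / {age_band}"
        )
    baseline = acc["h0"] / total_w
    inc_haly = (acc["h1"] - acc["h0"]) / total_w
    inc_cost = (acc["c1"] - acc["c0"]) / total_w
    return {
        "baseline_haly_per_case": baseline,
        "inc_haly_per_case": inc_haly,
        "inc_cost_per_case": inc_cost,
        "annual_cases": total_w,
        "population": pop_at_risk,
        "haly_per_100k": per_100k(inc_haly, total_w, pop_at_risk),
    }


def run_model_grid(
    bundle: ParameterBundle,
    cancers: Iterable[str] | None = None,
    scenarios: Iterable[ScenarioSpec] | None = None,
    age_bands: Sequence[str] = DEFAULT_REPORT_BANDS,
    reference_ethnicity: str = "non_maori",
) -> pd.DataFrame:
    """Full cross of cancer × scenario × ethnicity × age band.

    Returns a tidy frame with per-case baseline and incremental HALYs,
    incremental costs, percentage change against Model 1, ICERs, gains
    per 100,000 population-at-risk, and Māori/non-Māori relative risks.
    """
    cancers = list(cancers) if cancers is not None else list(CANCERS)
    scenarios = list(scenarios) if scenarios is not None else canonical_scenarios()

    records = []
    for cancer in cancers:
        for scenario in scenarios:
            for eth in ETHNICITIES:
                for band in age_bands:
                    cell = _cell_summary(
                        bundle, cancer, scenario, eth, band, reference_ethnicity
                    )
                    icer = compute_icer(
                        cell["inc_cost_per_case"], cell["inc_haly_per_case"]
                    )
                    records.append(
                        {
                            "cancer": cancer,
                            "model_id": scenario.model_id,
                            "ethnicity": eth,
                            "age_band": band,
                            **cell,
                            "icer": icer.value,
                            "icer_flag": icer.flag,
                        }
                    )
    df = pd.DataFrame.from_records(records)

    # percentage change of incremental HALYs per case against Model 1
    base_ids = df["model_id"] == min(s.model_id for s in scenarios)
    ref = df[base_ids].set_index(["cancer", "ethnicity", "age_band"])[
        "inc_haly_per_case"
    ]
    df["pct_change_vs_model1"] = [
        pct_change(v, ref.loc[(c, e, b)])
        for v, c, e, b in zip(
            df["inc_haly_per_case"], df["cancer"], df["ethnicity"], df["age_band"]
        )
    ]

    # Māori / non-Māori relative risks of the incremental gain
    nm = df[df["ethnicity"] == reference_ethnicity].set_index(
        ["cancer", "model_id", "age_band"]
    )
    rr_case, rr_pop = [], []
    for row in df.itertuples():
        if row.ethnicity == reference_ethnicity:
            rr_case.append(float("nan"))
            rr_pop.append(float("nan"))
        else:
            ref_row = nm.loc[(row.cancer, row.model_id, row.age_band)]
            rr_case.append(rr(row.inc_haly_per_case, ref_row["inc_haly_per_case"]))
            rr_pop.append(rr(row.haly_per_100k, ref_row["haly_per_100k"]))
    df["rr_per_case"] = rr_case
    df["rr_per_100k"] = rr_pop
    return df


def reporting_view(df: pd.DataFrame) -> pd.DataFrame:
    """Reporting-precision wide view: HALYs to 2 dp, % change to 1 dp,
    RRs to 2 dp, ICERs to the nearest NZ$100; one row per
    cancer × ethnicity × model, age bands across columns."""
    out = df.copy()
    out["baseline_haly_per_case"] = out["baseline_haly_per_case"].round(2)
    out["inc_haly_per_case"] = out["inc_haly_per_case"].round(2)
    out["pct_change_vs_model1"] = out["pct_change_vs_model1"].round(1)
    out["rr_per_case"] = out["rr_per_case"].round(2)
    out["rr_per_100k"] = out["rr_per_100k"].round(2)
    out["haly_per_100k"] = out["haly_per_100k"].round(0)
    out["icer"] = (out["icer"] / 100.0).round(0) * 100
    wide = out.pivot_table(
        index=["cancer", "ethnicity", "model_id"],
        columns="age_band",
        values=[
            "haly_per_100k",
            "baseline_haly_per_case",
            "inc_haly_per_case",
            "pct_change_vs_model1",
            "icer",
        ],
        sort=False,
    )
    wide.columns = [f"{band}|{metric}" for metric, band in wide.columns]
    return wide.reset_index()


def sensitivity_grid(
    bundle: ParameterBundle,
    cost_values: Sequence[float],
    effect_values: Sequence[float],
    cancers: Iterable[str] | None = None,
    scenario: ScenarioSpec | None = None,
    age_bands: Sequence[str] = ("65-69",),
    reference_ethnicity: str = "non_maori",
) -> pd.DataFrame:
    """Two-way sensitivity surface over direct monthly cost and effect size.

    Returns one ICER row per cancer × ethnicity × age band × (cost,
    effect) pair; an effect of zero yields an undefined-ICER flag rather
    than an error.  Defaults to the full-heterogeneity scenario.
    """
    if not len(cost_values) or not len(effect_values):
        raise ValueError("cost and effect grids must be non-empty")
    cancers = list(cancers) if cancers is not None else list(CANCERS)
    if scenario is None:
        scenario = canonical_scenarios()[-1]

    records = []
    for cancer in cancers:
        for cost in cost_values:
            for effect in effect_values:
                iv = InterventionSpec(
                    effect=effect,
                    direct_monthly_cost=cost,
                    discount_rate=bundle.intervention.discount_rate,
                )
                for eth in ETHNICITIES:
                    for band in age_bands:
                        cell = _cell_summary(
                            bundle, cancer, scenario, eth, band,
                            reference_ethnicity, intervention=iv,
                        )
                        icer = compute_icer(
                            cell["inc_cost_per_case"], cell["inc_haly_per_case"]
                        )
                        records.append(
                            {
                                "cancer": cancer,
                                "ethnicity": eth,
                                "age_band": band,
                                "direct_monthly_cost": cost,
                                "effect": effect,
                                "inc_haly_per_case": cell["inc_haly_per_case"],
                                "inc_cost_per_case": cell["inc_cost_per_case"],
                                "icer": icer.value,
                                "icer_flag": icer.flag,
                            }
                        )
    return pd.DataFrame.from_records(records)
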