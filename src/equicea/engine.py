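"""Monthly-cycle three-state Markov cohort engine.

A cohort diagnosed with cancer occupies one living state and two
absorbing states (death from the cancer, death from other causes).
Each monthly cycle combines the cancer's excess-mortality rate (zero
after the statistical-cure time) with the projected background rate in
a competing-risks split, and accumulates the probability of entering
each absorbing state at each month.  The run ends at the horizon age;
remaining probability mass is reported as alive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lifetable import competing_split, monthly_background_series
from .params import EffectiveParams, InterventionSpec, LifeTable
from .strata import band_midpoint

HORIZON_AGE = 110.0


@dataclass
class AbsorptionDistribution:
    """Per-month absorption probabilities from diagnosis to the horizon.

    ``p_cancer_death[t-1]`` and ``p_other_death[t-1]`` are the
    unconditional probabilities of dying in month t since diagnosis;
    ``p_alive`` is the mass surviving to the horizon.  The grand total
    is 1.
    """

    p_cancer_death: np.ndarray
    p_other_death: np.ndarray
    p_alive: float
    start_age: float

    @property
    def n_months(self) -> int:
        return len(self.p_cancer_death)

    def total(self) -> float:
        return float(self.p_cancer_death.sum() + self.p_other_death.sum() + self.p_alive)

    def cumulative_cancer_death(self) -> float:
        return float(self.p_cancer_death.sum())


def apply_intervention(m_excess, effect: float):
    """Scale an excess-mortality rate by the intervention's proportional
    reduction: ``m × (1 − effect)``."""
    if not 0.0 <= effect <= 1.0:
        raise ValueError(f"intervention effect {effect} outside [0, 1]")
    return np.asarray(m_excess, dtype=float) * (1.0 - effect)


def excess_hazard_constant_until_cure(
    annual_rate: float, cure_months: int, n_months: int
) -> np.ndarray:
    """Monthly excess-mortality hazard: constant (annual/12) through the
    statistical-cure time, exactly zero afterwards.

    This is the default hazard shape; ``run_cohort`` accepts any
    precomputed monthly hazard array in its place, so a shape declining
    with time since diagnosis can be swapped in.
    """
    m = np.zeros(n_months)
    m[: min(cure_months, n_months)] = annual_rate / 12.0
    return m


def run_cohort(
    effective: EffectiveParams,
    life_table: LifeTable,
    entry_year: int = 2006,
    intervention: InterventionSpec | None = None,
    intervention_on: bool = False,
    start_age: float | None = None,
    horizon_age: float = HORIZON_AGE,
    excess_monthly: np.ndarray | None = None,
) -> AbsorptionDistribution:
    """Run the cohort from diagnosis at ``start_age`` to the horizon age.

    ``start_age`` defaults to the midpoint of the stratum's 5-year age
    band.  With ``intervention_on`` the excess hazard is scaled by
    ``1 − effect`` in every cycle in which it is nonzero.
    """
    if start_age is None:
        start_age = band_midpoint(effective.stratum.age_band)
    if start_age >= horizon_age:
        raise ValueError(f"start_age {start_age} must be below horizon {horizon_age}")
    n_months = int(round((horizon_age - start_age) * 12))

    m_b = monthly_background_series(
        life_table,
        start_age,
        effective.stratum.sex,
        effective.background_ethnicity,
        entry_year,
        n_months,
    )
    if excess_monthly is None:
        m_e = excess_hazard_constant_until_cure(
            effective.excess_annual_rate, effective.schedule.cure_months, n_months
        )
    else:
        m_e = np.asarray(excess_monthly, dtype=float)
        if len(m_e) != n_months:
            raise ValueError(
                f"excess_monthly has {len(m_e)} cycles, expected {n_months}"
            )
    if intervention_on:
        if intervention is None:
            raise ValueError("intervention_on requires an InterventionSpec")
        m_e = apply_intervention(m_e, intervention.effect)

    for name, arr in (("excess", m_e), ("background", m_b)):
        bad = ~np.isfinite(arr)
        if bad.any():
            cycle = int(np.argmax(bad)) + 1
            raise ValueError(f"non-finite {name} rate at cycle {cycle}")

    p_c, p_o, p_s = competing_split(m_e, m_b)
    survival = np.concatenate([[1.0], np.cumprod(p_s)])
    return AbsorptionDistribution(
        p_cancer_death=survival[:-1] * p_c,
        p_other_death=survival[:-1] * p_o,
        p_alive=float(survival[-1]),
        start_age=start_age,
    )


def simulate_cohort_mc(
    effective: EffectiveParams,
    life_table: LifeTable,
    n_individuals: int,
    rng: np.random.Generator,
    entry_year: int = 2006,
    intervention: InterventionSpec | None = None,
    intervention_on: bool = False,
    start_age: float | None = None,
    horizon_age: float = HORIZON_AGE,
) -> AbsorptionDistribution:
    """Individual-level Monte-Carlo counterpart of :func:`run_cohort`.

    Simulates each person month by month with Bernoulli draws from the
    same per-cycle cause-specific probabilities and tallies empirical
    absorption frequencies.  Used as a stochastic oracle in validation;
    the deterministic cohort engine is the primary implementation.
    """
    if start_age is None:
        start_age = band_midpoint(effective.stratum.age_band)
    n_months = int(round((horizon_age - start_age) * 12))
    m_b = monthly_background_series(
        life_table, start_age, effective.stratum.sex,
        effective.background_ethnicity, entry_year, n_months,
    )
    m_e = excess_hazard_constant_until_cure(
        effective.excess_annual_rate, effective.schedule.cure_months, n_months
    )
    if intervention_on:
        assert intervention is not None
        m_e = apply_intervention(m_e, intervention.effect)
    p_c, p_o, _ = competing_split(m_e, m_b)

    alive = np.arange(n_individuals)
    cancer_deaths = np.zeros(n_months, dtype=np.int64)
    other_deaths = np.zeros(n_months, dtype=np.int64)
    for t in range(n_months):
        if alive.size == 0:
            break
        u = rng.random(alive.size)
        died_cancer = u < p_c[t]
        died_other = ~died_cancer & (u < p_c[t] + p_o[t])
        cancer_deaths[t] = int(died_cancer.sum())
        other_deaths[t] = int(died_other.sum())
        alive = alive[~(died_cancer | died_other)]
    n = float(n_individuals)
    return AbsorptionDistribution(
        p_cancer_death=cancer_deaths / n,
        p_other_death=other_deaths / n,
        p_alive=alive.size / n,
        start_age=start_age,
    )
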