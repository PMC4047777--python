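"""Background-mortality projection and rate→probability conversion.

Annual all-cause rates are projected forward with a fixed percentage
decline per calendar year up to a horizon year (after which rates are
frozen), divided by 12 to a monthly rate, and combined with the cancer's
excess-mortality rate in a competing-risks split each cycle.
"""

from __future__ import annotations

import numpy as np

from .params import LifeTable
from .strata import MAX_AGE


def project_background_rate(
    lt: LifeTable, age: float, sex: str, ethnicity: str, calendar_year: int
) -> float:
    """Monthly background mortality rate at an attained age and calendar year.

    The annual rate for the integer age is scaled by
    ``(1 - decline)^k`` where ``k`` is years since ``base_year`` capped at
    the decline horizon, then divided by 12.
    """
    if age > MAX_AGE:
        raise ValueError(f"age {age} exceeds the life-table maximum {MAX_AGE}")
    if calendar_year < lt.base_year:
        raise ValueError(
            f"calendar_year {calendar_year} precedes the life-table base year "
            f"{lt.base_year}"
        )
    years = min(calendar_year - lt.base_year, lt.decline_horizon_year - lt.base_year)
    annual = lt.annual_rate(int(age), sex, ethnicity)
    decline = lt.annual_decline[ethnicity]
    return annual * (1.0 - decline) ** years / 12.0


def monthly_background_series(
    lt: LifeTable,
    start_age: float,
    sex: str,
    ethnicity: str,
    entry_year: int,
    n_months: int,
) -> np.ndarray:
    """Vector of monthly background rates for cycles 1..n_months.

    Cycle t uses the age and calendar year attained at the start of the
    cycle (entry age plus t−1 elapsed months).
    """
    t = np.arange(n_months)
    ages = np.minimum((start_age + t / 12.0).astype(int), MAX_AGE)
    years = entry_year + t // 12
    k = np.minimum(years - lt.base_year, lt.decline_horizon_year - lt.base_year)
    if (k < 0).any():
        raise ValueError("entry_year precedes the life-table base year")
    decline = lt.annual_decline[ethnicity]
    annual = lt.rates[(ethnicity, sex)][ages]
    return annual * (1.0 - decline) ** k / 12.0


def rate_to_prob(m):
    """Convert a monthly rate to a monthly probability, 1 − exp(−m)."""
    m = np.asarray(m, dtype=float)
    if (m < 0).any():
        raise ValueError("rates must be non-negative")
    out = -np.expm1(-m)
    return float(out) if out.ndim == 0 else out


def competing_split(m_cancer, m_background):
    """One-cycle competing-risks split of two cause-specific rates.

    Total exit probability is ``1 − exp(−(m_c + m_b))``, allocated to the
    two causes proportionally to their rates; the triple
    (p_cancer_death, p_other_death, p_survive) sums to 1.  Accepts scalars
    or arrays.
    """
    m_c = np.asarray(m_cancer, dtype=float)
    m_b = np.asarray(m_background, dtype=float)
    if (m_c < 0).any() or (m_b < 0).any():
        raise ValueError("rates must be non-negative")
    total = m_c + m_b
    p_survive = np.exp(-total)
    p_exit = -np.expm1(-total)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, m_c / np.where(total > 0, total, 1.0), 0.0)
    p_cancer = p_exit * frac
    p_other = p_exit - p_cancer
    if p_cancer.ndim == 0:
        return float(p_cancer), float(p_other), float(p_survive)
    return p_cancer, p_other, p_survive
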