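"""Retrospective phase trajectories and their HALY / cost valuation.

Once the engine has decided *when* and *of what* a cohort member died
(or that they survived to the horizon), the disease trajectory is
reconstructed backwards from that outcome:

* cancer deaths end in a terminal month preceded by a pre-terminal
  period, with diagnosis/treatment at the front and remission filling
  the gap (end-anchored truncation when death comes early);
* other-cause deaths and survivors follow diagnosis → remission →
  statistically cured, with other-cause deaths additionally carrying
  elevated costs (and, optionally, terminal-phase morbidity) in their
  final months of life.

Each month is then valued as a health-adjusted life year (HALY)
fraction — a life-year weighted by (1 − disability weight) for the
cancer phase and capped by the background-morbidity envelope
(1 − pYLD) — and as NZ$ health-system cost, both discounted to
diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import CostTable, DisabilityWeightSet, PhaseSchedule
from .strata import band_index_of_age

OUTCOMES = ("cancer_death", "other_death", "survivor")

_LAST_MONTHS_OF_LIFE = 6


@dataclass
class Trajectory:
    """Monthly phase sequence from diagnosis to death or the horizon."""

    outcome: str
    phases: np.ndarray  # dtype str, one slot per lived month
    last6: np.ndarray  # other-cause deaths: final months-of-life flag
    start_age: float

    @property
    def n_months(self) -> int:
        return len(self.phases)

    def attained_ages(self) -> np.ndarray:
        """Age at the start of each lived month."""
        return self.start_age + np.arange(self.n_months) / 12.0


def build_trajectory(
    outcome: str,
    death_month: int | None,
    schedule: PhaseSchedule,
    total_months: int,
    start_age: float = 0.0,
) -> Trajectory:
    """Reconstruct the phase sequence for one absorbing outcome.

    For a cancer death at month ``d`` the last ``terminal_months`` months
    are terminal, the ``preterminal_months`` before them pre-terminal, the
    first ``diagnosis_months`` diagnosis, and any gap remission.  When
    death comes too early for all phases, end-anchored precedence applies:
    terminal first, then pre-terminal, then a truncated diagnosis phase.

    Survivors and other-cause deaths follow the front-anchored sequence
    diagnosis → remission (until the statistical-cure month) → cured;
    other-cause deaths flag their final six months of life.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    if outcome == "survivor":
        if death_month is not None:
            raise ValueError("survivors have no death month")
        length = total_months
    else:
        if death_month is None:
            raise ValueError(f"{outcome} requires a death month")
        if not 1 <= death_month <= total_months:
            raise ValueError(
                f"death month {death_month} outside 1..{total_months}"
            )
        length = death_month

    phases = np.empty(length, dtype="<U11")
    last6 = np.zeros(length, dtype=bool)

    if outcome == "cancer_death":
        n_term = min(schedule.terminal_months, length)
        n_pre = min(schedule.preterminal_months, length - n_term)
        n_diag = min(schedule.diagnosis_months, length - n_term - n_pre)
        phases[:n_diag] = "diagnosis"
        phases[n_diag : length - n_term - n_pre] = "remission"
        phases[length - n_term - n_pre : length - n_term] = "preterminal"
        phases[length - n_term :] = "terminal"
    else:
        n_diag = min(schedule.diagnosis_months, length)
        phases[:n_diag] = "diagnosis"
        phases[n_diag : min(schedule.cure_months, length)] = "remission"
        phases[min(schedule.cure_months, length) :] = "cured"
        if outcome == "other_death":
            last6[max(0, length - _LAST_MONTHS_OF_LIFE) :] = True

    return Trajectory(outcome=outcome, phases=phases, last6=last6, start_age=start_age)


def discount_factor(t, annual_rate: float):
    """Discount factor ``(1 + r)^(−t/12)`` for value accruing at the end
    of month t since diagnosis."""
    if annual_rate < 0:
        raise ValueError("discount rate must be non-negative")
    t = np.asarray(t, dtype=float)
    out = (1.0 + annual_rate) ** (-t / 12.0)
    return float(out) if out.ndim == 0 else out


def haly_weight(
    phase: str,
    dw_set: DisabilityWeightSet,
    pyld: float,
    dw_on: bool = True,
    pyld_on: bool = True,
) -> float:
    """Health weight for one month: ``(1 − dw) × (1 − pYLD)``.

    The cancer's phase disability weight scales the health remaining
    after background morbidity; the (1 − pYLD) factor is the maximum
    envelope of health attainable in the stratum.  The cured phase
    carries no cancer disability weight.
    """
    dw = dw_set.weight(phase) if dw_on else 0.0
    p = pyld if pyld_on else 0.0
    return (1.0 - dw) * (1.0 - p)


def _phase_dw_vector(
    traj: Trajectory, dw_set: DisabilityWeightSet, other_death_terminal_dw: bool
) -> np.ndarray:
    dw_map = {
        "diagnosis": dw_set.diagnosis,
        "remission": dw_set.remission,
        "preterminal": dw_set.preterminal,
        "terminal": dw_set.terminal,
        "cured": 0.0,
    }
    dw = np.array([dw_map[p] for p in traj.phases])
    if traj.outcome == "other_death" and other_death_terminal_dw and len(dw):
        # elevated end-of-life morbidity for non-cancer deaths
        dw[-1] = dw_set.terminal
    return dw


def value_halys(
    traj: Trajectory,
    dw_set: DisabilityWeightSet,
    pyld_by_band: np.ndarray,
    annual_rate: float = 0.03,
    dw_on: bool = True,
    pyld_on: bool = True,
    other_death_terminal_dw: bool = True,
) -> float:
    """Discounted HALYs of one trajectory.

    Each lived month contributes ``haly_weight / 12`` discounted to
    diagnosis; pYLD is looked up at the attained 5-year age band
    (clamped to the top band past age 94).
    """
    if traj.n_months == 0:
        return 0.0
    months = np.arange(1, traj.n_months + 1)
    disc = discount_factor(months, annual_rate)
    dw = _phase_dw_vector(traj, dw_set, other_death_terminal_dw) if dw_on else 0.0
    pyld = pyld_by_band[band_index_of_age(traj.attained_ages())] if pyld_on else 0.0
    weights = (1.0 - dw) * (1.0 - pyld)
    return float(np.sum(weights / 12.0 * disc))


def value_costs(
    traj: Trajectory,
    cost_table: CostTable,
    cancer: str,
    sex: str,
    intervention_on: bool = False,
    direct_monthly_cost: float = 0.0,
    annual_rate: float = 0.03,
) -> float:
    """Discounted health-system plus intervention cost of one trajectory.

    Each month carries the cancer's phase-specific monthly cost (zero
    once cured), one twelfth of the background annual cost at the
    attained age band — replaced by the pro-rated last-six-months-of-life
    cost in flagged months of other-cause deaths — and the intervention's
    direct monthly cost during the diagnosis/treatment phase when the
    intervention is on.
    """
    if traj.n_months == 0:
        return 0.0
    months = np.arange(1, traj.n_months + 1)
    disc = discount_factor(months, annual_rate)
    band_idx = band_index_of_age(traj.attained_ages())

    phase_cost = np.array(
        [cost_table.phase_cost(cancer, p) for p in traj.phases]
    )
    bg = cost_table.background_by_band(sex)[band_idx] / 12.0
    last6 = cost_table.last6_by_band(sex)[band_idx] / 6.0
    monthly = phase_cost + np.where(traj.last6, last6, bg)
    if intervention_on:
        monthly = monthly + direct_monthly_cost * (traj.phases == "diagnosis")
    return float(np.sum(monthly * disc))
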