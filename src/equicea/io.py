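"""Bundle serialisation: one directory of UTF-8 CSVs plus a YAML settings file.

Layout::

    bundle_dir/
      incidence.csv          cancer, ethnicity, sex, age_band, deprivation, value
      excess_mortality.csv   (same columns)
      life_table.csv         age, sex, ethnicity, rate
      pyld.csv               ethnicity, sex, age_band, value
      population.csv         ethnicity, sex, age_band, count
      costs_background.csv   age_band, sex, annual_cost, last_six_months_cost
      costs_cancer.csv       cancer, phase, monthly_cost
      settings.yaml          phase schedules, disability weights, intervention,
                             deprivation weights, life-table projection settings
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .params import (
    CostTable,
    DeprivationWeights,
    DisabilityWeightSet,
    InterventionSpec,
    LifeTable,
    ParameterBundle,
    PhaseSchedule,
    PopulationTable,
    PyldTable,
    RateTable,
)
from .strata import CANCERS, SEXES, AGE_BANDS

_FILES = (
    "incidence.csv",
    "excess_mortality.csv",
    "life_table.csv",
    "pyld.csv",
    "population.csv",
    "costs_background.csv",
    "costs_cancer.csv",
    "settings.yaml",
)


def _read(path: Path) -> pd.DataFrame:
    # round_trip parsing so written bundles reload bit-identically
    return pd.read_csv(path, float_precision="round_trip")


def write_bundle(bundle: ParameterBundle, path: str | Path) -> Path:
    """Write a bundle to a directory (created if absent); returns the path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    for fname, tables in (
        ("incidence.csv", bundle.incidence),
        ("excess_mortality.csv", bundle.excess_mortality),
    ):
        frames = []
        for cancer in CANCERS:
            df = tables[cancer].to_frame()
            df.insert(0, "cancer", cancer)
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(path / fname, index=False)

    bundle.life_table.to_frame().to_csv(path / "life_table.csv", index=False)
    bundle.pyld.to_frame().to_csv(path / "pyld.csv", index=False)
    bundle.population.to_frame().to_csv(path / "population.csv", index=False)

    rows = [
        (band, sex, bundle.costs.background(band, sex), bundle.costs.last6(band, sex))
        for band in AGE_BANDS
        for sex in SEXES
    ]
    pd.DataFrame(
        rows, columns=["age_band", "sex", "annual_cost", "last_six_months_cost"]
    ).to_csv(path / "costs_background.csv", index=False)

    rows = [
        (cancer, phase, cost)
        for cancer in CANCERS
        for phase, cost in sorted(bundle.costs.cancer_monthly[cancer].items())
    ]
    pd.DataFrame(rows, columns=["cancer", "phase", "monthly_cost"]).to_csv(
        path / "costs_cancer.csv", index=False
    )

    settings = {
        "entry_year": bundle.entry_year,
        "life_table": {
            "base_year": bundle.life_table.base_year,
            "annual_decline": dict(bundle.life_table.annual_decline),
            "decline_horizon_year": bundle.life_table.decline_horizon_year,
        },
        "phase_schedules": {
            c: bundle.phase_schedules[c].model_dump() for c in CANCERS
        },
        "disability_weights": {
            c: bundle.disability_weights[c].model_dump() for c in CANCERS
        },
        "intervention": bundle.intervention.model_dump(),
        "deprivation_weights": {
            "maori": list(bundle.deprivation_weights.maori),
            "non_maori": list(bundle.deprivation_weights.non_maori),
        },
    }
    (path / "settings.yaml").write_text(
        yaml.safe_dump(settings, sort_keys=True), encoding="utf-8"
    )
    return path


def read_bundle(path: str | Path) -> ParameterBundle:
    """Read a bundle directory written by :func:`write_bundle`."""
    path = Path(path)
    missing = [f for f in _FILES if not (path / f).exists()]
    if missing:
        raise FileNotFoundError(
            f"bundle at {path} is missing file(s): {', '.join(missing)}"
        )

    settings = yaml.safe_load((path / "settings.yaml").read_text(encoding="utf-8"))

    def rate_tables(fname: str, kind: str) -> dict[str, RateTable]:
        df = _read(path / fname)
        return {
            cancer: RateTable.from_frame(grp, kind, f"{kind}[{cancer}]")
            for cancer, grp in df.groupby("cancer")
        }

    lt_meta = settings["life_table"]
    life_table = LifeTable.from_frame(
        _read(path / "life_table.csv"),
        base_year=int(lt_meta["base_year"]),
        annual_decline={k: float(v) for k, v in lt_meta["annual_decline"].items()},
        decline_horizon_year=int(lt_meta["decline_horizon_year"]),
    )

    bg = _read(path / "costs_background.csv")
    cc = _read(path / "costs_cancer.csv")
    costs = CostTable(
        background_annual={
            (r.age_band, r.sex): float(r.annual_cost) for r in bg.itertuples()
        },
        last_six_months={
            (r.age_band, r.sex): float(r.last_six_months_cost) for r in bg.itertuples()
        },
        cancer_monthly={
            cancer: {r.phase: float(r.monthly_cost) for r in grp.itertuples()}
            for cancer, grp in cc.groupby("cancer")
        },
    )

    return ParameterBundle(
        incidence=rate_tables("incidence.csv", "incidence"),
        excess_mortality=rate_tables("excess_mortality.csv", "excess_mortality"),
        life_table=life_table,
        pyld=PyldTable.from_frame(_read(path / "pyld.csv")),
        phase_schedules={
            c: PhaseSchedule(**v) for c, v in settings["phase_schedules"].items()
        },
        disability_weights={
            c: DisabilityWeightSet(**v)
            for c, v in settings["disability_weights"].items()
        },
        costs=costs,
        intervention=InterventionSpec(**settings["intervention"]),
        deprivation_weights=DeprivationWeights(
            maori=tuple(settings["deprivation_weights"]["maori"]),
            non_maori=tuple(settings["deprivation_weights"]["non_maori"]),
        ),
        population=PopulationTable.from_frame(_read(path / "population.csv")),
        entry_year=int(settings["entry_year"]),
    )
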