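"""Socio-demographic stratification grid.

Every rate table in the model is indexed by the cell
ethnicity × sex × 5-year age band × area-deprivation tertile.
Age bands cover the modelled diagnosis ages 45–49 through 90–94;
attained ages beyond the top band (people surviving past 94) are
clamped to the top band for band-level lookups (morbidity, costs),
while single-year life-table lookups use the exact integer age.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

ETHNICITIES = ("maori", "non_maori")
SEXES = ("female", "male")
DEPRIVATION_TERTILES = ("dep1_3", "dep4_6", "dep7_10")
AGE_BANDS = (
    "45-49",
    "50-54",
    "55-59",
    "60-64",
    "65-69",
    "70-74",
    "75-79",
    "80-84",
    "85-89",
    "90-94",
)
CANCERS = ("lung", "breast", "colon")

#: breast cancer is modelled for females only
CANCER_SEXES = {
    "lung": SEXES,
    "breast": ("female",),
    "colon": SEXES,
}

MAX_AGE = 110

_BAND_LOWER = np.array([int(b.split("-")[0]) for b in AGE_BANDS])


class StratumKey(NamedTuple):
    """One socio-demographic cell of the parameter grid."""

    ethnicity: str
    sex: str
    age_band: str
    deprivation: str

    def validate(self) -> "StratumKey":
        if self.ethnicity not in ETHNICITIES:
            raise ValueError(f"unknown ethnicity {self.ethnicity!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.age_band not in AGE_BANDS:
            raise ValueError(f"unknown age band {self.age_band!r}")
        if self.deprivation not in DEPRIVATION_TERTILES:
            raise ValueError(f"unknown deprivation tertile {self.deprivation!r}")
        return self


def band_midpoint(age_band: str) -> float:
    """Midpoint age of a 5-year band, e.g. 52.5 for '50-54'."""
    lo, hi = age_band.split("-")
    return (int(lo) + int(hi) + 1) / 2.0


def band_index_of_age(age):
    """Index into AGE_BANDS for an attained age (scalar or array).

    Ages above the top band are clamped to the top band; ages below
    45 are clamped to the bottom band (they do not occur for cohorts
    entering at 45+).
    """
    age = np.asarray(age)
    idx = (age.astype(int) - 45) // 5
    return np.clip(idx, 0, len(AGE_BANDS) - 1)


def band_of_age(age: float) -> str:
    return AGE_BANDS[int(band_index_of_age(age))]


def stratum_grid(cancer: str | None = None):
    """All StratumKeys, restricted to the sexes a cancer applies to."""
    sexes = CANCER_SEXES[cancer] if cancer is not None else SEXES
    return [
        StratumKey(e, s, b, d)
        for e in ETHNICITIES
        for s in sexes
        for b in AGE_BANDS
        for d in DEPRIVATION_TERTILES
    ]
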