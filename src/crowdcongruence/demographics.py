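"""Construction of the six district-level sociodemographic covariates.

Covariates: birthrate (births per fertile woman), mean and SD of married
women's educational attainment (years of schooling), population density
(persons per m^2, i.e. population / (area_km2 * 1e6)), doctors per
pediatric clinic, and availability (clinics per 1000 residents).

The density unit deserves a note: official district areas are in km^2 but
the covariate is scaled as millions of persons per km^2 (equivalently
persons per m^2), which puts metropolitan districts in the 0.003-0.029
range.  The unit only rescales the corresponding regression coefficient;
standardized coefficients and p-values are unchanged.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import pandas as pd

#: Years of schooling for each educational-attainment category.
EDUCATION_YEARS: dict[str, int] = {
    "none": 0,
    "elementary": 6,
    "middle": 9,
    "high": 12,
    "college_2yr": 14,
    "college_4yr": 16,
    "master": 18,
    "phd": 23,
}

EDUCATION_CATEGORIES = list(EDUCATION_YEARS)


@dataclass(frozen=True)
class DistrictDemographics:
    district_id: str
    birthrate: float
    education_mean: float
    education_sd: float
    population: float
    area_km2: float
    population_density: float
    doctors_per_clinic: float
    availability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.education_mean <= 23.0:
            raise ValueError(
                f"education_mean out of range for {self.district_id}: "
                f"{self.education_mean}"
            )
        for name in (
            "birthrate",
            "education_sd",
            "population",
            "area_km2",
            "population_density",
            "doctors_per_clinic",
            "availability",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative for {self.district_id}")


def education_stats(
    category_counts: Mapping[str, float] | Sequence[float],
) -> tuple[float, float]:
    """Weighted mean and population SD of years of schooling.

    ``category_counts`` is either a mapping from category name (see
    ``EDUCATION_YEARS``) to a non-negative count, or a sequence of eight
    counts in category order.  The SD divides by the total count (census
    populations, not samples).
    """
    if isinstance(category_counts, Mapping):
        unknown = set(category_counts) - set(EDUCATION_YEARS)
        if unknown:
            raise KeyError(f"unknown education categories: {sorted(unknown)}")
        items = [(EDUCATION_YEARS[c], n) for c, n in category_counts.items()]
    else:
        if len(category_counts) != len(EDUCATION_CATEGORIES):
            raise ValueError(
                f"expected {len(EDUCATION_CATEGORIES)} counts, got {len(category_counts)}"
            )
        items = list(zip(EDUCATION_YEARS.values(), category_counts))
    if any(n < 0 for _, n in items):
        raise ValueError("category counts must be non-negative")
    total = sum(n for _, n in items)
    if total <= 0:
        raise ValueError("total education count must be positive")
    mean = sum(y * n for y, n in items) / total
    var = sum(n * (y - mean) ** 2 for y, n in items) / total
    return mean, math.sqrt(var)


def build_features(
    district_id: str,
    population: float,
    area_km2: float,
    n_clinics: int,
    n_doctors: int,
    birthrate: float,
    education: Mapping[str, float] | Sequence[float] | tuple[float, float],
) -> DistrictDemographics:
    """Assemble one district's covariate record from raw census inputs.

    ``education`` is either category counts (passed to
    :func:`education_stats`) or a precomputed ``(mean_years, sd_years)``
    pair.
    """
    if area_km2 <= 0:
        raise ValueError(f"district {district_id}: area must be positive")
    if n_clinics <= 0:
        raise ValueError(f"district {district_id}: n_clinics must be positive")
    if population <= 0:
        raise ValueError(f"district {district_id}: population must be positive")
    if (
        isinstance(education, tuple)
        and len(education) == 2
        and all(isinstance(v, (int, float)) for v in education)
    ):
        edu_mean, edu_sd = float(education[0]), float(education[1])
    else:
        edu_mean, edu_sd = education_stats(education)
    return DistrictDemographics(
        district_id=district_id,
        birthrate=birthrate,
        education_mean=edu_mean,
        education_sd=edu_sd,
        population=population,
        area_km2=area_km2,
        population_density=population / (area_km2 * 1e6),
        doctors_per_clinic=n_doctors / n_clinics,
        availability=1000.0 * n_clinics / population,
    )


def aggregate_periods(
    tables: Sequence[pd.DataFrame],
    methods: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Collapse per-period district tables to one table.

    Default per-column method is the arithmetic mean across periods
    (population, area, birthrate, prescription rates); ``methods`` may map
    a column to ``"first"`` for pass-through quantities observed in a
    single period (education).  Tables must share index (district) and
    columns.
    """
    if len(tables) == 0:
        raise ValueError("need at least one period")
    first = tables[0]
    for t in tables[1:]:
        if not t.index.equals(first.index) or list(t.columns) != list(first.columns):
            raise ValueError("period tables must share index and columns")
    if len(tables) == 1:
        return first.copy()
    methods = dict(methods or {})
    out = {}
    for col in first.columns:
        how = methods.get(col, "mean")
        if how == "mean":
            out[col] = sum(t[col] for t in tables) / len(tables)
        elif how == "first":
            out[col] = first[col]
        else:
            raise ValueError(f"unknown aggregation method {how!r} for column {col!r}")
    return pd.DataFrame(out, index=first.index)


def demographics_frame(records: Sequence[DistrictDemographics]) -> pd.DataFrame:
    """Tabulate covariate records, one row per district."""
    rows = [
        {
            "district_id": d.district_id,
            "birthrate": d.birthrate,
            "education_mean": d.education_mean,
            "education_sd": d.education_sd,
            "population": d.population,
            "area_km2": d.area_km2,
            "population_density": d.population_density,
            "doctors_per_clinic": d.doctors_per_clinic,
            "availability": d.availability,
        }
        for d in records
    ]
    return pd.DataFrame(rows).set_index("district_id")
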