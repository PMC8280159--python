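"""Stratum-level data model, table IO and cohort-matched lagged exposure lookup.

The statistical unit is a demographic stratum: (country, registry, age group,
gender) observed in one outcome year, carrying a case count and a population
at risk.  Exposure histories are assembled by walking a cohort backwards in
time: the exposure at lag ``l`` for a stratum observed in year ``t`` is the
panel value for calendar year ``t - l`` in the 5-year age band that contains
``lower_age_bound - l``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import MissingPanelDataError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: The eight outcome age bands, ordered.
AGE_BANDS = (
    "40-44", "45-49", "50-54", "55-59", "60-64", "65-69", "70-74", "75-79",
)

GENDERS = ("F", "M")

#: Canonical column names of a long-format strata table.
STRATA_COLUMNS = (
    "country", "registry", "age_group", "gender", "outcome_year",
    "cases", "population",
)

PANEL_COLUMNS = ("country", "gender", "age_band", "year", "prevalence")


def band_lower(band: str) -> int:
    """Lower age bound of a 5-year band label such as ``"40-44"``."""
    return int(band.split("-")[0])


def band_of(age: int) -> str:
    """The 5-year band label containing integer age ``age``."""
    lo = 5 * (age // 5)
    return f"{lo}-{lo + 4}"


@dataclass(frozen=True)
class StrataRecord:
    """One demographic stratum-year with its outcome and person-time."""

    country: str
    registry: str
    age_group: str
    gender: str
    outcome_year: int
    cases: int
    population: float

    def validate(self, age_bands: Sequence[str] = AGE_BANDS,
                 year_range: tuple[int, int] | None = None) -> None:
        if self.cases < 0:
            raise ValidationError(f"cases must be >= 0, got {self.cases}")
        if not self.population > 0:
            raise ValidationError(
                f"population must be > 0, got {self.population}")
        if self.age_group not in age_bands:
            raise ValidationError(
                f"age_group {self.age_group!r} not one of {list(age_bands)}")
        if self.gender not in GENDERS:
            raise ValidationError(f"gender must be 'M' or 'F', got {self.gender!r}")
        if year_range is not None and not (
                year_range[0] <= self.outcome_year <= year_range[1]):
            raise ValidationError(
                f"outcome_year {self.outcome_year} outside {year_range}")

    @property
    def stratum_id(self) -> str:
        """Stable identifier used to key per-stratum RNG streams."""
        return (f"{self.country}|{self.registry}|{self.age_group}"
                f"|{self.gender}|{self.outcome_year}")


@dataclass(frozen=True)
class ExposureHistory:
    """Exposure (% prevalence) at lags 0..lag_max, backward in time."""

    values: np.ndarray
    lag_max: int

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (self.lag_max + 1,):
            raise ValidationError(
                f"history length {vals.shape} != lag_max+1 = {self.lag_max + 1}")
        if not np.all(np.isfinite(vals)):
            raise ValidationError("exposure history contains missing values")
        if vals.min() < 0 or vals.max() > 100:
            raise ValidationError("exposure values must lie in [0, 100]")


@dataclass
class PrevalencePanel:
    """Prevalence (%) keyed by (country, gender, age_band, calendar_year)."""

    values: dict[tuple[str, str, str, int], float]
    year_range: tuple[int, int]
    age_bands: tuple[str, ...]

    def get(self, country: str, gender: str, band: str, year: int) -> float:
        try:
            return self.values[(country, gender, band, year)]
        except KeyError:
            raise MissingPanelDataError(
                f"no prevalence for (country={country}, gender={gender}, "
                f"band={band}, year={year})") from None

    def to_dataframe(self) -> pd.DataFrame:
        rows = [(c, g, b, y, v) for (c, g, b, y), v in self.values.items()]
        df = pd.DataFrame(rows, columns=list(PANEL_COLUMNS))
        return df.sort_values(list(PANEL_COLUMNS[:4])).reset_index(drop=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PrevalencePanel":
        missing = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"panel table missing columns: {missing}")
        vals = {}
        for row in df.itertuples(index=False):
            p = float(row.prevalence)
            if not (0.0 <= p <= 100.0):
                raise ValidationError(
                    f"prevalence {p} outside [0, 100] for "
                    f"({row.country}, {row.gender}, {row.age_band}, {row.year})")
            vals[(str(row.country), str(row.gender), str(row.age_band),
                  int(row.year))] = p
        years = [k[3] for k in vals]
        bands = sorted({k[2] for k in vals}, key=band_lower)
        return cls(values=vals, year_range=(min(years), max(years)),
                   age_bands=tuple(bands))


def _load_schema(schema_config) -> Mapping[str, str]:
    """Column mapping canonical-name -> file column; identity by default."""
    if schema_config is None:
        return {c: c for c in STRATA_COLUMNS}
    if isinstance(schema_config, (str, Path)):
        with open(schema_config) as fh:
            schema_config = yaml.safe_load(fh)
    mapping = dict(schema_config.get("columns", schema_config))
    out = {c: mapping.get(c, c) for c in STRATA_COLUMNS}
    return out


def read_strata_table(path, schema_config=None,
                      year_range: tuple[int, int] | None = None
                      ) -> list[StrataRecord]:
    """Read and validate a long-format strata CSV.

    Parameters
    ----------
    path : path to a CSV with one row per stratum-year.
    schema_config : optional mapping (or YAML file) renaming canonical
        columns (``country`` .. ``population``) to the file's column names.
    year_range : optional inclusive (min, max) bound on outcome_year.
    """
    mapping = _load_schema(schema_config)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [src for src in mapping.values() if src not in df.columns]
    if missing:
        raise SchemaError(f"strata table {path} missing columns: {missing}")
    records: list[StrataRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row_d = row._asdict()
        try:
            rec = StrataRecord(
                country=str(row_d[mapping["country"]]),
                registry=str(row_d[mapping["registry"]]),
                age_group=str(row_d[mapping["age_group"]]),
                gender=str(row_d[mapping["gender"]]),
                outcome_year=int(row_d[mapping["outcome_year"]]),
                cases=int(row_d[mapping["cases"]]),
                population=float(row_d[mapping["population"]]),
            )
            rec.validate(year_range=year_range)
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
        records.append(rec)
    logger.info("read %d strata records from %s", len(records), path)
    return records


def write_strata_table(records: Iterable[StrataRecord], path) -> None:
    df = pd.DataFrame([{
        "country": r.country, "registry": r.registry,
        "age_group": r.age_group, "gender": r.gender,
        "outcome_year": r.outcome_year, "cases": r.cases,
        "population": r.population,
    } for r in records])
    df.to_csv(path, index=False)
    logger.info("wrote %d strata records to %s", len(df), path)


def read_panel_table(path) -> PrevalencePanel:
    df = pd.read_csv(path, float_precision="round_trip")
    panel = PrevalencePanel.from_dataframe(df)
    logger.info("read prevalence panel (%d cells) from %s",
                len(panel.values), path)
    return panel


def write_panel_table(panel: PrevalencePanel, path) -> None:
    panel.to_dataframe().to_csv(path, index=False)


def cohort_lagged_exposure(panel: PrevalencePanel, record: StrataRecord,
                           lag_max: int = 30) -> ExposureHistory:
    """Cohort-matched lagged exposure history for one stratum.

    Element ``l`` is the panel prevalence at calendar year
    ``outcome_year - l`` for the 5-year age band containing
    ``lower_bound(age_group) - l``; lags that are not multiples of 5 fall
    inside a band (no interpolation).
    """
    lo = band_lower(record.age_group)
    vals = np.empty(lag_max + 1)
    for l in range(lag_max + 1):
        vals[l] = panel.get(record.country, record.gender,
                            band_of(lo - l), record.outcome_year - l)
    return ExposureHistory(values=vals, lag_max=lag_max)


def build_histories(panel: PrevalencePanel, records: Sequence[StrataRecord],
                    lag_max: int = 30) -> list[ExposureHistory]:
    """Vector of cohort-matched histories aligned with ``records``."""
    return [cohort_lagged_exposure(panel, r, lag_max) for r in records]
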