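"""Domain types, table I/O and descriptive statistics for the soil-Cr pipeline.

The unit of analysis is an *industrial region*: one location with a measured
total soil chromium concentration (``cr_conc``, mg/kg), an industry-type code,
and province/year metadata.  Industry types follow the six-code scheme used
throughout the package:

====  =============================================
code  industry
====  =============================================
M     mining areas
S     heavy-metal processing and smelting areas
E-w   e-waste dismantling areas
El    electroplating areas
T     tanning areas
C     chromium-salt production areas
====  =============================================

Concentrations are compared against a geochemical background value ``Bn``
(provincial where available, national default 61 mg/kg) and a regulatory
screening value (default 2500 mg/kg for industrial land, total Cr).
"""

from __future__ import annotations

import datetime
import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "INDUSTRY_TYPES",
    "REGION_TABLE_COLUMNS",
    "NATIONAL_BACKGROUND_CR",
    "DEFAULT_SCREENING_VALUE",
    "DEFAULT_TOXIC_RESPONSE",
    "RegionRecord",
    "BackgroundTable",
    "AssessmentConfig",
    "SummaryStats",
    "SchemaError",
    "RowError",
    "EmptyInputError",
    "read_region_table",
    "write_region_table",
    "lookup_background",
    "describe",
    "load_config",
]

#: Valid industry-type codes.
INDUSTRY_TYPES = ("M", "S", "E-w", "El", "T", "C")

#: Canonical CSV column order for region tables.
REGION_TABLE_COLUMNS = (
    "region_id",
    "province",
    "city",
    "industry_type",
    "sampling_year",
    "depth_cm",
    "cr_conc",
    "source",
)

#: National soil Cr background value, mg/kg.
NATIONAL_BACKGROUND_CR = 61.0

#: Screening value for total Cr in industrial soils, mg/kg.
DEFAULT_SCREENING_VALUE = 2500.0

#: Hakanson toxic response coefficient for Cr.
DEFAULT_TOXIC_RESPONSE = 2.0

_MIN_YEAR = 1990


class SchemaError(ValueError):
    """A table is missing required columns or has an unusable header."""


class RowError(ValueError):
    """One or more rows violate record invariants; message lists row numbers."""


class EmptyInputError(ValueError):
    """An operation requiring data received an empty collection."""


@dataclass(frozen=True)
class RegionRecord:
    """One industrial region's soil Cr measurement.

    ``cr_conc`` must be strictly positive: a zero concentration has no
    geoaccumulation index, so non-detects must be substituted (e.g. half the
    detection limit) before they enter the pipeline.
    """

    region_id: str
    province: str
    industry_type: str
    cr_conc: float
    city: str | None = None
    sampling_year: int | None = None
    depth_cm: float | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if self.industry_type not in INDUSTRY_TYPES:
            raise ValueError(
                f"industry_type {self.industry_type!r} not one of {INDUSTRY_TYPES}"
            )
        if not (self.cr_conc > 0):
            raise ValueError(f"cr_conc must be > 0, got {self.cr_conc!r}")
        if self.sampling_year is not None:
            this_year = datetime.date.today().year
            if not (_MIN_YEAR <= self.sampling_year <= this_year):
                raise ValueError(
                    f"sampling_year {self.sampling_year} outside "
                    f"[{_MIN_YEAR}, {this_year}]"
                )
        if self.depth_cm is not None and self.depth_cm < 0:
            raise ValueError(f"depth_cm must be >= 0, got {self.depth_cm}")


@dataclass(frozen=True)
class BackgroundTable:
    """Province-keyed soil Cr background values with a national fallback."""

    per_province: Mapping[str, float] = field(default_factory=dict)
    national_default: float = NATIONAL_BACKGROUND_CR

    def __post_init__(self) -> None:
        if not (self.national_default > 0):
            raise ValueError("national_default must be > 0")
        for prov, bn in self.per_province.items():
            if not (bn > 0):
                raise ValueError(f"background for {prov!r} must be > 0, got {bn}")

    def lookup(self, province: str) -> float:
        return self.per_province.get(province, self.national_default)


@dataclass(frozen=True)
class SummaryStats:
    """Descriptive statistics of a set of region concentrations (mg/kg)."""

    n: int
    min: float
    max: float
    mean: float
    median: float
    sd: float
    cv_pct: float
    pct_above_background: float
    pct_above_screening: float


@dataclass(frozen=True)
class AssessmentConfig:
    """Bundle of assessment parameters shared by all pipeline stages.

    ``receptor_profiles``/``toxicity``/``mc_spec`` are filled by the
    health-risk and Monte-Carlo stages; they are carried here so one config
    document drives the whole pipeline.
    """

    screening_value: float = DEFAULT_SCREENING_VALUE
    toxic_response_coefficient: float = DEFAULT_TOXIC_RESPONSE
    background: BackgroundTable = field(default_factory=BackgroundTable)
    area_map: Mapping[str, str] | None = None
    receptor_profiles: Sequence = ()
    toxicity: object | None = None
    mc_spec: object | None = None

    def __post_init__(self) -> None:
        if not (self.screening_value > 0):
            raise ValueError("screening_value must be > 0")
        if not (self.toxic_response_coefficient > 0):
            raise ValueError("toxic_response_coefficient must be > 0")


# ---------------------------------------------------------------------------
# region-table I/O


def _parse_optional_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def _parse_optional_str(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def read_region_table(path_or_stream) -> list[RegionRecord]:
    """Read a region table CSV into validated :class:`RegionRecord` objects.

    Required columns: ``region_id``, ``province``, ``industry_type``,
    ``cr_conc``.  Rows violating record invariants are collected and reported
    together in a single :class:`RowError` naming the offending row numbers
    (1-based over data rows).
    """
    df = pd.read_csv(path_or_stream, dtype={"region_id": str, "province": str})
    required = {"region_id", "province", "industry_type", "cr_conc"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"missing required column(s): {sorted(missing)}")

    records: list[RegionRecord] = []
    problems: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        try:
            cr = float(d["cr_conc"])
        except (TypeError, ValueError):
            problems.append(f"row {i}: cr_conc {d['cr_conc']!r} is not numeric")
            continue
        year = d.get("sampling_year")
        try:
            year = None if pd.isna(year) else int(year)
        except (TypeError, ValueError):
            problems.append(f"row {i}: sampling_year {year!r} is not an integer")
            continue
        itype = str(d["industry_type"]).strip()
        try:
            records.append(
                RegionRecord(
                    region_id=str(d["region_id"]),
                    province=str(d["province"]),
                    city=_parse_optional_str(d.get("city")),
                    industry_type=itype,
                    sampling_year=year,
                    depth_cm=_parse_optional_float(d.get("depth_cm")),
                    cr_conc=cr,
                    source=_parse_optional_str(d.get("source")),
                )
            )
        except ValueError as exc:
            problems.append(f"row {i}: {exc}")
    if problems:
        raise RowError("; ".join(problems))
    return records


def write_region_table(records: Iterable[RegionRecord], path_or_stream) -> None:
    """Write records as the canonical region-table CSV (UTF-8, header row)."""
    rows = [
        {
            "region_id": r.region_id,
            "province": r.province,
            "city": r.city,
            "industry_type": r.industry_type,
            "sampling_year": r.sampling_year,
            "depth_cm": r.depth_cm,
            "cr_conc": r.cr_conc,
            "source": r.source,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=list(REGION_TABLE_COLUMNS))
    df.to_csv(path_or_stream, index=False)


def lookup_background(table: BackgroundTable, province: str) -> float:
    """Return the province's background Cr value, or the national default."""
    return table.lookup(province)


# ---------------------------------------------------------------------------
# descriptive statistics


def describe(
    records: Sequence[RegionRecord],
    background: BackgroundTable,
    screening: float = DEFAULT_SCREENING_VALUE,
) -> SummaryStats:
    """Descriptive statistics over ``cr_conc`` plus exceedance percentages.

    The standard deviation uses the unbiased (n-1) denominator, and the
    coefficient of variation is ``100*sd/mean``.  Both exceedance percentages
    use strict ``>``; the background comparison resolves each record's own
    provincial background.
    """
    if len(records) == 0:
        raise EmptyInputError("describe requires at least one record")
    conc = np.array([r.cr_conc for r in records], dtype=float)
    bn = np.array([background.lookup(r.province) for r in records], dtype=float)
    n = conc.size
    mean = float(conc.mean())
    sd = float(conc.std(ddof=1)) if n > 1 else 0.0
    return SummaryStats(
        n=n,
        min=float(conc.min()),
        max=float(conc.max()),
        mean=mean,
        median=float(np.median(conc)),
        sd=sd,
        cv_pct=100.0 * sd / mean,
        pct_above_background=100.0 * float(np.mean(conc > bn)),
        pct_above_screening=100.0 * float(np.mean(conc > screening)),
    )


# ---------------------------------------------------------------------------
# config loading


def load_config(path_or_stream) -> dict:
    """Load a YAML assessment-config document into a plain dict.

    Schema (all keys optional; defaults applied downstream)::

        screening_value: 2500
        toxic_response_coefficient: 2
        background:
          national_default: 61
          per_province: {Zhejiang: 52.9, ...}
        area_map: {Zhejiang: "Yangtze River Delta", ...}
        receptors: [{group: child, IngR: 200, ...}, ...]
        toxicity: {rfd_ing: 3.0e-3, rfd_derm: 7.5e-5, rfd_inh: 2.86e-5}
        mc: {n_iter: 10000, distributions: {cn: {kind: lognormal, ...}}}
    """
    if isinstance(path_or_stream, (str,)) or hasattr(path_or_stream, "__fspath__"):
        with open(path_or_stream, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    elif isinstance(path_or_stream, io.IOBase) or hasattr(path_or_stream, "read"):
        doc = yaml.safe_load(path_or_stream)
    else:
        raise TypeError("load_config expects a path or a readable stream")
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise SchemaError("config document must be a mapping")
    return doc


def background_from_config(doc: Mapping) -> BackgroundTable:
    """Build a :class:`BackgroundTable` from a loaded config dict."""
    bg = doc.get("background") or {}
    return BackgroundTable(
        per_province={str(k): float(v) for k, v in (bg.get("per_province") or {}).items()},
        national_default=float(bg.get("national_default", NATIONAL_BACKGROUND_CR)),
    )
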