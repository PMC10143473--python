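"""Hotspot-area aggregation and yearly-median temporal trend fitting.

Industrial soil Cr pollution clusters in five areas -- the Yangtze River
Delta, the Bohai Rim, the Pearl River Delta, the Yangtze River Basin and
the Yellow River Basin.  Regions are assigned to areas through a
province-to-area map (a default map ships with the package, fully
overridable); pollution-class distributions and screening-value exceedance
shares are then compared across areas.

The temporal trend is estimated from the yearly median concentration:
medians are log10-transformed (the raw data being strongly right-skewed)
and a quadratic in calendar year is fitted by ordinary least squares on
centered years.  A negative leading coefficient gives a single interior
peak -- the rise-then-fall pattern with a turning point near 2009 seen in
national industrial soil Cr records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core_data import RegionRecord
from .pollution_indices import E_CLASS_LABELS, IndexResult

__all__ = [
    "AREAS",
    "DEFAULT_AREA_MAP",
    "AreaAssignment",
    "TrendFit",
    "assign_areas",
    "area_class_distribution",
    "exceedance_by_area",
    "yearly_medians",
    "fit_trend",
]

#: Area labels in priority order: delta/rim labels outrank basin labels, so a
#: province a user map lists under two areas resolves to the earlier one.
AREAS = (
    "Yangtze River Delta",
    "Bohai Rim",
    "Pearl River Delta",
    "Yangtze River Basin",
    "Yellow River Basin",
    "other",
)

#: Default province -> area map (standard provincial membership).
DEFAULT_AREA_MAP: Mapping[str, str] = {
    "Shanghai": "Yangtze River Delta",
    "Jiangsu": "Yangtze River Delta",
    "Zhejiang": "Yangtze River Delta",
    "Anhui": "Yangtze River Delta",
    "Beijing": "Bohai Rim",
    "Tianjin": "Bohai Rim",
    "Hebei": "Bohai Rim",
    "Shandong": "Bohai Rim",
    "Liaoning": "Bohai Rim",
    "Guangdong": "Pearl River Delta",
    "Hubei": "Yangtze River Basin",
    "Hunan": "Yangtze River Basin",
    "Jiangxi": "Yangtze River Basin",
    "Sichuan": "Yangtze River Basin",
    "Chongqing": "Yangtze River Basin",
    "Henan": "Yellow River Basin",
    "Shaanxi": "Yellow River Basin",
    "Shanxi": "Yellow River Basin",
    "Gansu": "Yellow River Basin",
    "Inner Mongolia": "Yellow River Basin",
    "Ningxia": "Yellow River Basin",
    "Qinghai": "Yellow River Basin",
}


@dataclass(frozen=True)
class AreaAssignment:
    region_id: str
    area: str


@dataclass(frozen=True)
class TrendFit:
    """Quadratic fit of log10(yearly median concentration) on calendar year.

    ``coefficients`` are (a, b, c) of ``a*year**2 + b*year + c`` in calendar
    years (de-centered from the internal centered fit); ``vertex_year`` is
    ``-b/(2a)``, absent when the curvature is numerically zero.
    """

    coefficients: tuple[float, float, float]
    vertex_year: float | None
    r_squared: float
    n_years: int


def assign_areas(
    records: Sequence[RegionRecord],
    area_map: Mapping[str, str | Sequence[str]] | None = None,
) -> list[AreaAssignment]:
    """Map each region to exactly one hotspot area via its province.

    ``area_map`` maps province -> area (or a sequence of areas, resolved by
    the priority order of :data:`AREAS` with a warning).  Unknown provinces
    fall back to ``"other"``.
    """
    area_map = DEFAULT_AREA_MAP if area_map is None else area_map
    resolved: dict[str, str] = {}
    for prov, area in area_map.items():
        if isinstance(area, str):
            resolved[prov] = area
        else:
            ordered = sorted(set(area), key=AREAS.index)
            if len(ordered) > 1:
                warnings.warn(
                    f"province {prov!r} listed in {ordered}; using {ordered[0]!r}"
                )
            resolved[prov] = ordered[0]
    return [
        AreaAssignment(r.region_id, resolved.get(r.province, "other"))
        for r in records
    ]


def area_class_distribution(
    assignments: Sequence[AreaAssignment],
    results: Sequence[IndexResult],
) -> dict[str, dict]:
    """Per-area I_geo-class and E-class fractions (summing to 1 per area)."""
    if len(assignments) != len(results):
        raise ValueError("assignments and results must be aligned")
    by_area: dict[str, list[IndexResult]] = {}
    for asg, res in zip(assignments, results):
        by_area.setdefault(asg.area, []).append(res)
    out: dict[str, dict] = {}
    for area in AREAS:
        group = by_area.get(area)
        if not group:
            continue
        n = len(group)
        out[area] = {
            "n": n,
            "igeo_class_fractions": {
                k: sum(1 for g in group if g.igeo_class == k) / n for k in range(7)
            },
            "e_class_fractions": {
                lab: sum(1 for g in group if g.e_class == lab) / n
                for lab in E_CLASS_LABELS
            },
        }
    return out


def exceedance_by_area(
    records: Sequence[RegionRecord],
    assignments: Sequence[AreaAssignment],
    screening: float,
) -> dict[str, dict]:
    """Counts and shares of screening-value exceedances per area.

    ``share_pct`` is each area's percentage of the total exceedance count;
    all zeros when nothing exceeds.  A ``"total"`` entry carries the overall
    count.
    """
    if len(records) != len(assignments):
        raise ValueError("records and assignments must be aligned")
    counts = {area: 0 for area in AREAS}
    total = 0
    for rec, asg in zip(records, assignments):
        if rec.cr_conc > screening:
            counts[asg.area] += 1
            total += 1
    out = {
        area: {
            "count": c,
            "share_pct": (100.0 * c / total) if total else 0.0,
        }
        for area, c in counts.items()
    }
    out["total"] = {"count": total, "share_pct": 100.0 if total else 0.0}
    return out


def yearly_medians(records: Sequence[RegionRecord]) -> dict[int, float]:
    """Median ``cr_conc`` per sampling year, in ascending year order.

    Records without a sampling year are skipped; the even-n median is the
    mean of the two middle values.  Empty (with a warning) when no record
    carries a year.
    """
    by_year: dict[int, list[float]] = {}
    for r in records:
        if r.sampling_year is not None:
            by_year.setdefault(r.sampling_year, []).append(r.cr_conc)
    if not by_year:
        warnings.warn("no dated records; yearly medians empty")
        return {}
    return {y: float(np.median(by_year[y])) for y in sorted(by_year)}


def fit_trend(
    medians: Mapping[int, float],
    degree: int = 2,
    log_base: float = 10.0,
    zero_tol: float = 1e-12,
) -> TrendFit:
    """OLS quadratic fit of log(median) on calendar year.

    Years are centered before fitting to keep the normal equations
    well-conditioned, then coefficients are de-centered back to calendar
    years.  ``degree`` and ``log_base`` generalise the default
    quadratic-on-log10 model (e.g. ``degree=3`` or ``log_base=np.e``);
    ``vertex_year`` is only reported for the quadratic.
    """
    if len(medians) < max(3, degree + 1):
        raise ValueError(
            f"fit_trend needs at least {max(3, degree + 1)} distinct years, "
            f"got {len(medians)}"
        )
    years = np.array(sorted(medians), dtype=float)
    vals = np.array([medians[int(y)] for y in years])
    if np.any(vals <= 0):
        raise ValueError("medians must be positive for log transformation")
    logm = np.log(vals) / np.log(log_base)

    c0 = years.mean()
    coef_centered = np.polyfit(years - c0, logm, deg=degree)
    # de-center via polynomial composition with (year - c0)
    p = np.polynomial.Polynomial(coef_centered[::-1])
    shifted = p(np.polynomial.Polynomial([-c0, 1.0]))
    full = shifted.coef  # ascending order, calendar years
    full = np.pad(full, (0, degree + 1 - len(full)))

    fitted = np.polyval(coef_centered, years - c0)
    ss_res = float(np.sum((logm - fitted) ** 2))
    ss_tot = float(np.sum((logm - logm.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    if degree == 2:
        a, b, c = float(full[2]), float(full[1]), float(full[0])
        vertex = None if abs(a) < zero_tol else -b / (2.0 * a)
        coefs = (a, b, c)
    else:
        coefs = tuple(float(x) for x in full[::-1])
        vertex = None
    return TrendFit(
        coefficients=coefs,
        vertex_year=vertex,
        r_squared=r2,
        n_years=len(medians),
    )
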