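"""Geoaccumulation index and single-metal potential ecological risk index.

Two classical soil-pollution indices, both relative to the geochemical
background ``Bn``:

* the Muller geoaccumulation index
  ``I_geo = log2(Cn / (1.5 * Bn))``, where the factor 1.5 absorbs natural
  lithogenic variation of the baseline; and
* the Hakanson monomial potential ecological risk index
  ``E = Tn * Cn / Bn``, the contamination factor ``Cn/Bn`` weighted by the
  metal's toxic response coefficient (``Tn = 2`` for Cr).

The two are linked by the exact identity ``I_geo = log2(E / (1.5 * Tn))``.

Class schemes (both overridable via the ``boundaries`` arguments):

* ``I_geo``: seven classes, class 0 for ``I_geo <= 0`` (unpolluted) up to
  class 6 for ``I_geo > 5`` (extremely contaminated); interior classes are
  the unit intervals ``(k-1, k]``.
* ``E``: low < 40 <= moderate < 80 <= considerable < 160 <= high < 320 <=
  significant high.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core_data import (
    DEFAULT_TOXIC_RESPONSE,
    BackgroundTable,
    RegionRecord,
    lookup_background,
)

__all__ = [
    "IGEO_CLASS_LABELS",
    "E_CLASS_LABELS",
    "E_CLASS_BOUNDS",
    "IndexResult",
    "igeo",
    "ecological_risk",
    "classify_igeo",
    "classify_e",
    "assess_regions",
    "summarize_by_type",
]

IGEO_CLASS_LABELS = (
    "unpolluted",
    "unpolluted to moderately polluted",
    "moderately polluted",
    "moderately to heavily polluted",
    "heavily polluted",
    "heavily to extremely polluted",
    "extremely polluted",
)

E_CLASS_LABELS = ("low", "moderate", "considerable", "high", "significant high")

#: Lower-closed boundaries separating successive E classes.
E_CLASS_BOUNDS = (40.0, 80.0, 160.0, 320.0)


@dataclass(frozen=True)
class IndexResult:
    """Pollution-index results for a single region."""

    region_id: str
    igeo: float
    igeo_class: int
    e_value: float
    e_class: str
    bn_used: float


def igeo(cn: float, bn: float) -> float:
    """Geoaccumulation index log2(cn / (1.5 * bn)).

    Parameters are the measured concentration and the background value, both
    mg/kg and strictly positive.
    """
    if not (cn > 0) or not (bn > 0):
        raise ValueError(f"igeo requires cn > 0 and bn > 0, got cn={cn}, bn={bn}")
    return math.log2(cn / (1.5 * bn))


def ecological_risk(cn: float, bn: float, tn: float = DEFAULT_TOXIC_RESPONSE) -> float:
    """Monomial potential ecological risk index tn * cn / bn."""
    if not (cn > 0) or not (bn > 0) or not (tn > 0):
        raise ValueError(
            f"ecological_risk requires positive inputs, got cn={cn}, bn={bn}, tn={tn}"
        )
    return tn * cn / bn


def classify_igeo(value: float) -> int:
    """Map an I_geo value to its class 0-6 (upper-closed interior intervals)."""
    if math.isnan(value):
        raise ValueError("igeo value is NaN")
    if value <= 0:
        return 0
    if value > 5:
        return 6
    # class k covers (k-1, k]
    return int(math.ceil(value))


def classify_e(value: float, bounds: Sequence[float] = E_CLASS_BOUNDS) -> str:
    """Map an E value to its ecological-risk label (lower-closed boundaries)."""
    if math.isnan(value):
        raise ValueError("E value is NaN")
    if value < 0:
        raise ValueError(f"E must be >= 0, got {value}")
    idx = int(np.searchsorted(np.asarray(bounds, dtype=float), value, side="right"))
    return E_CLASS_LABELS[idx]


def assess_regions(
    records: Sequence[RegionRecord],
    background: BackgroundTable,
    tn: float = DEFAULT_TOXIC_RESPONSE,
) -> list[IndexResult]:
    """Compute I_geo and E with classes for every record, in input order.

    The background value is resolved per record from its province; the value
    actually used is recorded in ``bn_used`` so the provincial-vs-national
    choice stays auditable.
    """
    results = []
    for rec in records:
        bn = lookup_background(background, rec.province)
        try:
            ig = igeo(rec.cr_conc, bn)
            e = ecological_risk(rec.cr_conc, bn, tn)
        except ValueError as exc:
            raise ValueError(f"region {rec.region_id!r}: {exc}") from exc
        results.append(
            IndexResult(
                region_id=rec.region_id,
                igeo=ig,
                igeo_class=classify_igeo(ig),
                e_value=e,
                e_class=classify_e(e),
                bn_used=bn,
            )
        )
    return results


def summarize_by_type(
    results: Sequence[IndexResult],
    records: Sequence[RegionRecord],
) -> dict[str, dict]:
    """Per-industry-type means and class-distribution fractions.

    Returns ``{type: {"n", "mean_igeo", "mean_e", "igeo_class_fractions",
    "e_class_fractions"}}``.  Class fractions are proportions (summing to 1
    within each type); types with no regions are omitted with a warning.
    """
    if len(results) != len(records):
        raise ValueError("results and records must be aligned")
    by_type: dict[str, list[IndexResult]] = {}
    for res, rec in zip(results, records):
        by_type.setdefault(rec.industry_type, []).append(res)

    summary: dict[str, dict] = {}
    from .core_data import INDUSTRY_TYPES

    for itype in INDUSTRY_TYPES:
        group = by_type.get(itype)
        if not group:
            warnings.warn(f"industry type {itype!r} has no regions; omitted")
            continue
        n = len(group)
        igeo_fracs: Mapping[int, float] = {
            k: sum(1 for g in group if g.igeo_class == k) / n for k in range(7)
        }
        e_fracs = {
            lab: sum(1 for g in group if g.e_class == lab) / n
            for lab in E_CLASS_LABELS
        }
        summary[itype] = {
            "n": n,
            "mean_igeo": float(np.mean([g.igeo for g in group])),
            "mean_e": float(np.mean([g.e_value for g in group])),
            "igeo_class_fractions": igeo_fracs,
            "e_class_fractions": e_fracs,
        }
    return summary
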