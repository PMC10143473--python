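"""Deterministic non-carcinogenic health-risk model for soil Cr exposure.

Implements the standard regulatory soil-exposure dose model for three
receptor groups (children, adult males, adult females) and three pathways:

* soil ingestion:        ``ADD_ing  = Cn*IngR*EF*ED*CF / (BW*AT)``
* dermal contact:        ``ADD_derm = Cn*SA*AF*ABS*EF*ED*CF / (BW*AT)``
* particulate inhalation:``ADD_inh  = Cn*InhR*EF*ED / (PEF*BW*AT)``

with Cn the soil concentration (mg/kg), CF = 1e-6 kg/mg, and PEF the
particulate emission factor (m3/kg).  Each pathway's hazard quotient is
``HQ_x = ADD_x / RfD_x``; the reported HQ is their sum (a single-metal
hazard index), and HQ > 1 flags a potential non-carcinogenic concern.

Carcinogenic risk (which would require Cr(VI) speciation) is out of scope.

The shipped receptor and toxicity defaults are repository defaults drawn
from the USEPA Exposure Factors Handbook and Chinese HJ 25.3 conventions
(e.g. child soil ingestion 200 mg/day, body weight 15 kg, PEF 1.36e9 m3/kg;
oral RfD 3e-3 mg/(kg*day) for Cr(VI), conservative for total Cr, dermal RfD
= oral x 2.5% gastrointestinal absorption).  Every parameter is a plain
dataclass field and fully overridable from config.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "RECEPTOR_GROUPS",
    "ReceptorProfile",
    "ToxicityParams",
    "HealthRiskResult",
    "default_receptors",
    "default_toxicity",
    "add_ingestion",
    "add_dermal",
    "add_inhalation",
    "hazard_quotients",
    "summarize_hq",
]

RECEPTOR_GROUPS = ("child", "adult_male", "adult_female")

#: kg per mg.
CF_KG_PER_MG = 1e-6


@dataclass(frozen=True)
class ReceptorProfile:
    """Exposure parameters for one receptor group.

    Units: IngR mg/day; InhR m3/day; SA cm2; AF mg/(cm2*day); ABS
    dimensionless fraction; EF days/year; ED years; BW kg; AT days;
    PEF m3/kg; CF kg/mg.
    """

    group: str
    IngR: float
    InhR: float
    SA: float
    AF: float
    ABS: float
    EF: float
    ED: float
    BW: float
    AT: float
    PEF: float = 1.36e9
    CF: float = CF_KG_PER_MG

    def __post_init__(self) -> None:
        for name in ("IngR", "InhR", "SA", "AF", "ABS", "EF", "ED", "BW", "AT",
                     "PEF", "CF"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.ABS > 1:
            raise ValueError(f"ABS must be <= 1, got {self.ABS}")


@dataclass(frozen=True)
class ToxicityParams:
    """Pathway-specific reference doses, mg/(kg*day)."""

    rfd_ing: float = 3.0e-3
    rfd_derm: float = 7.5e-5
    rfd_inh: float = 2.86e-5

    def __post_init__(self) -> None:
        for name in ("rfd_ing", "rfd_derm", "rfd_inh"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class HealthRiskResult:
    """Per-region, per-group doses and hazard quotients."""

    region_id: str
    group: str
    add_ing: float
    add_derm: float
    add_inh: float
    hq_ing: float
    hq_derm: float
    hq_inh: float
    hq_total: float
    exceeds_1: bool


def default_receptors() -> tuple[ReceptorProfile, ...]:
    """Repository-default exposure profiles for the three receptor groups."""
    child = ReceptorProfile(
        group="child", IngR=200.0, InhR=7.6, SA=2800.0, AF=0.2, ABS=0.001,
        EF=350.0, ED=6.0, BW=15.0, AT=6 * 365.0,
    )
    male = ReceptorProfile(
        group="adult_male", IngR=100.0, InhR=19.0, SA=5700.0, AF=0.07,
        ABS=0.001, EF=350.0, ED=24.0, BW=70.0, AT=24 * 365.0,
    )
    female = ReceptorProfile(
        group="adult_female", IngR=100.0, InhR=14.5, SA=5300.0, AF=0.07,
        ABS=0.001, EF=350.0, ED=24.0, BW=60.0, AT=24 * 365.0,
    )
    return (child, male, female)


def default_toxicity() -> ToxicityParams:
    return ToxicityParams()


def _check_cn(cn) -> None:
    if not np.all(np.asarray(cn) > 0):
        raise ValueError(f"cn must be > 0, got {cn}")


def add_ingestion(cn, p: ReceptorProfile):
    """Average daily dose via incidental soil ingestion, mg/(kg*day).

    ``cn`` may be a scalar or array; the dose is linear in ``cn``.
    """
    _check_cn(cn)
    return cn * p.IngR * p.EF * p.ED * p.CF / (p.BW * p.AT)


def add_dermal(cn, p: ReceptorProfile):
    """Average daily dose via dermal contact with soil, mg/(kg*day)."""
    _check_cn(cn)
    return cn * p.SA * p.AF * p.ABS * p.EF * p.ED * p.CF / (p.BW * p.AT)


def add_inhalation(cn, p: ReceptorProfile):
    """Average daily dose via inhalation of resuspended particulates."""
    _check_cn(cn)
    return cn * p.InhR * p.EF * p.ED / (p.PEF * p.BW * p.AT)


def hazard_quotients(
    cn: float,
    p: ReceptorProfile,
    tox: ToxicityParams,
    region_id: str = "",
    pathways: Sequence[str] = ("ing", "derm", "inh"),
) -> HealthRiskResult:
    """Pathway hazard quotients and their sum for one concentration.

    ``pathways`` restricts which routes contribute to ``hq_total`` (e.g.
    ``("ing",)`` for an ingestion-only variant); excluded pathways report
    zero dose and HQ.
    """
    a_ing = add_ingestion(cn, p) if "ing" in pathways else 0.0
    a_derm = add_dermal(cn, p) if "derm" in pathways else 0.0
    a_inh = add_inhalation(cn, p) if "inh" in pathways else 0.0
    hq_ing = a_ing / tox.rfd_ing
    hq_derm = a_derm / tox.rfd_derm
    hq_inh = a_inh / tox.rfd_inh
    total = hq_ing + hq_derm + hq_inh
    return HealthRiskResult(
        region_id=region_id,
        group=p.group,
        add_ing=a_ing,
        add_derm=a_derm,
        add_inh=a_inh,
        hq_ing=hq_ing,
        hq_derm=hq_derm,
        hq_inh=hq_inh,
        hq_total=total,
        exceeds_1=bool(total > 1.0),
    )


def assess_health_risk(records, profiles=None, tox=None, pathways=("ing", "derm", "inh")):
    """Hazard quotients for every record x receptor group combination."""
    profiles = profiles if profiles is not None else default_receptors()
    tox = tox if tox is not None else default_toxicity()
    out: list[HealthRiskResult] = []
    for rec in records:
        for p in profiles:
            out.append(
                hazard_quotients(rec.cr_conc, p, tox, region_id=rec.region_id,
                                 pathways=pathways)
            )
    return out


def summarize_hq(
    results: Sequence[HealthRiskResult],
    types_by_region: Mapping[str, str] | None = None,
) -> dict:
    """Group-level (and optionally type-level) HQ summaries.

    Returns, per receptor group: mean HQ, the proportion (percent) of
    regions with HQ strictly above 1 and, when ``types_by_region`` maps
    region ids to industry types, per-type means plus each type's ratio to
    the all-region mean.  Ratios are computed from unrounded means.
    """
    if len(results) == 0:
        raise ValueError("summarize_hq requires at least one result")
    summary: dict = {}
    groups = sorted({r.group for r in results})
    for grp in groups:
        rs = [r for r in results if r.group == grp]
        if not rs:
            warnings.warn(f"group {grp!r} empty; omitted")
            continue
        hqs = np.array([r.hq_total for r in rs])
        entry: dict = {
            "n": len(rs),
            "mean_hq": float(hqs.mean()),
            "pct_above_1": 100.0 * float(np.mean(hqs > 1.0)),
        }
        if types_by_region is not None:
            national_mean = float(hqs.mean())
            by_type: dict[str, dict] = {}
            for r in rs:
                itype = types_by_region.get(r.region_id)
                if itype is None:
                    continue
                by_type.setdefault(itype, []).append(r.hq_total)
            entry["by_type"] = {
                itype: {
                    "n": len(vals),
                    "mean_hq": float(np.mean(vals)),
                    "pct_above_1": 100.0 * float(np.mean(np.array(vals) > 1.0)),
                    "ratio_to_national": float(np.mean(vals)) / national_mean,
                }
                for itype, vals in by_type.items()
            }
        summary[grp] = entry
    return summary
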