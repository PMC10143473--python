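"""Monte Carlo propagation of exposure and concentration uncertainty.

Exposure parameters and the soil concentration are assigned probability
distributions; each iteration draws every stochastic parameter, evaluates
the deterministic hazard-quotient model, and the resulting HQ sample is
summarised (mean, sd, percentiles, probability of exceeding 1).  The
default iteration count is 10,000.

One seeded ``numpy.random.Generator`` stream drives a run in a fixed
iteration order, so results are bit-reproducible from the seed regardless
of platform or parallelism.  Percentiles use the median-unbiased
(Hyndman-Fan type 8) estimator.

The module also supplies a rank (Spearman) sensitivity analysis of the HQ
sample against each stochastic parameter's draws, the standard companion
of spreadsheet-style probabilistic risk assessments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import stats

from .health_risk import ReceptorProfile, ToxicityParams

__all__ = [
    "DistributionSpec",
    "MCSpec",
    "MCResult",
    "sample",
    "run_mc",
    "rank_sensitivity",
]

_KINDS = ("point", "uniform", "normal", "lognormal", "triangular")


class ConfigError(ValueError):
    """A distribution or MC spec is invalid."""


@dataclass(frozen=True)
class DistributionSpec:
    """One parameter's sampling distribution.

    ``params`` by kind: point ``(value,)``; uniform ``(lo, hi)``; normal
    ``(mean, sd)``; lognormal ``(mu, sigma)`` of the underlying natural log;
    triangular ``(lo, mode, hi)``.  ``truncation`` optionally restricts
    support to ``[lo, hi]`` (inverse-CDF restriction for normal/lognormal,
    rejection otherwise).
    """

    kind: str
    params: tuple
    truncation: tuple | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigError(f"unknown distribution kind {self.kind!r}")
        p = self.params
        try:
            if self.kind == "point" and len(p) != 1:
                raise ConfigError("point requires (value,)")
            if self.kind == "uniform" and not (len(p) == 2 and p[0] < p[1]):
                raise ConfigError("uniform requires (lo, hi) with lo < hi")
            if self.kind in ("normal", "lognormal") and not (len(p) == 2 and p[1] > 0):
                raise ConfigError(f"{self.kind} requires (loc, scale) with scale > 0")
            if self.kind == "triangular" and not (
                len(p) == 3 and p[0] <= p[1] <= p[2] and p[0] < p[2]
            ):
                raise ConfigError("triangular requires lo <= mode <= hi, lo < hi")
        except TypeError as exc:
            raise ConfigError(f"bad params for {self.kind}: {p!r}") from exc
        if self.truncation is not None:
            lo, hi = self.truncation
            if not (lo < hi):
                raise ConfigError(f"truncation lo must be < hi, got {self.truncation}")


@dataclass(frozen=True)
class MCSpec:
    """Monte Carlo run configuration.

    ``distributions`` maps a parameter name (any :class:`ReceptorProfile`
    field, or ``"cn"`` for the soil concentration) to its
    :class:`DistributionSpec`; parameters not listed stay at their
    deterministic values.
    """

    n_iter: int = 10_000
    seed: int = 0
    distributions: Mapping[str, DistributionSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ConfigError(f"n_iter must be >= 1, got {self.n_iter}")


@dataclass(frozen=True)
class MCResult:
    """Summary of a sampled HQ distribution for one receptor group."""

    group: str
    n_iter: int
    seed: int
    mean: float
    sd: float
    p5: float
    p50: float
    p95: float
    prob_exceed_1: float
    draws: Mapping[str, np.ndarray] | None = None
    hq_draws: np.ndarray | None = None


def sample(dist: DistributionSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` i.i.d. values from ``dist`` using ``rng``."""
    p = dist.params
    trunc = dist.truncation
    if dist.kind == "point":
        out = np.full(n, float(p[0]))
    elif dist.kind == "normal" and trunc is not None:
        lo, hi = trunc
        a, b = (lo - p[0]) / p[1], (hi - p[0]) / p[1]
        out = stats.truncnorm.ppf(rng.uniform(size=n), a, b, loc=p[0], scale=p[1])
    elif dist.kind == "lognormal" and trunc is not None:
        lo, hi = trunc
        if hi <= 0:
            raise ConfigError("lognormal truncation has no positive mass")
        llo = -np.inf if lo <= 0 else (np.log(lo) - p[0]) / p[1]
        lhi = (np.log(hi) - p[0]) / p[1]
        z = stats.truncnorm.ppf(rng.uniform(size=n), llo, lhi)
        out = np.exp(p[0] + p[1] * z)
    else:
        if dist.kind == "uniform":
            draw = lambda m: rng.uniform(p[0], p[1], size=m)
        elif dist.kind == "normal":
            draw = lambda m: rng.normal(p[0], p[1], size=m)
        elif dist.kind == "lognormal":
            draw = lambda m: rng.lognormal(p[0], p[1], size=m)
        else:  # triangular
            draw = lambda m: rng.triangular(p[0], p[1], p[2], size=m)
        out = draw(n)
        if trunc is not None:  # rejection with a retry cap
            lo, hi = trunc
            for _ in range(1000):
                bad = (out < lo) | (out > hi)
                if not bad.any():
                    break
                out[bad] = draw(int(bad.sum()))
            else:
                raise ConfigError(
                    f"truncation {trunc} leaves negligible mass for {dist.kind}{p}"
                )
    if trunc is not None and dist.kind == "point":
        lo, hi = trunc
        if not (lo <= p[0] <= hi):
            raise ConfigError("point value outside truncation interval")
    return out


def run_mc(
    cn: float,
    profile: ReceptorProfile,
    tox: ToxicityParams,
    mc: MCSpec,
    store_draws: bool = False,
) -> MCResult:
    """Propagate parameter uncertainty through the hazard-quotient model.

    ``cn`` (and any receptor field) is replaced by draws from its
    distribution when one is listed in ``mc.distributions``; all remaining
    parameters are held at their deterministic values.  The summarised
    quantity is the total (all-pathway) HQ.
    """
    if mc.n_iter < 100:
        warnings.warn("n_iter < 100: percentile estimates will be unstable")
    rng = np.random.default_rng(mc.seed)
    n = mc.n_iter

    # draw in sorted parameter order so results are independent of dict order
    draws: dict[str, np.ndarray] = {}
    for name in sorted(mc.distributions):
        draws[name] = sample(mc.distributions[name], n, rng)

    cn_arr = draws.get("cn", np.full(n, float(cn)))
    if np.any(cn_arr <= 0):
        raise ConfigError("concentration draws must be positive; truncate the "
                          "distribution at 0")

    def pick(name: str) -> np.ndarray:
        return draws.get(name, np.full(n, float(getattr(profile, name))))

    IngR, InhR = pick("IngR"), pick("InhR")
    SA, AF, ABS = pick("SA"), pick("AF"), pick("ABS")
    EF, ED = pick("EF"), pick("ED")
    BW, AT, PEF = pick("BW"), pick("AT"), pick("PEF")
    CF = profile.CF

    denom = BW * AT
    hq = (
        cn_arr * IngR * EF * ED * CF / denom / tox.rfd_ing
        + cn_arr * SA * AF * ABS * EF * ED * CF / denom / tox.rfd_derm
        + cn_arr * InhR * EF * ED / (PEF * denom) / tox.rfd_inh
    )

    p5, p50, p95 = np.quantile(hq, [0.05, 0.50, 0.95], method="median_unbiased")
    return MCResult(
        group=profile.group,
        n_iter=n,
        seed=mc.seed,
        mean=float(hq.mean()),
        sd=float(hq.std(ddof=1)) if n > 1 else 0.0,
        p5=float(p5),
        p50=float(p50),
        p95=float(p95),
        prob_exceed_1=float(np.mean(hq > 1.0)),
        draws=draws if store_draws else None,
        hq_draws=hq if store_draws else None,
    )


def rank_sensitivity(result: MCResult) -> list[tuple[str, float]]:
    """Spearman rank correlation of each stochastic parameter with HQ.

    Requires a run made with ``store_draws=True``.  Returns ``(name, rho)``
    pairs sorted by decreasing ``|rho|``; point-mass (constant) parameters
    are skipped.  Empty (with a warning) when fewer than one varying
    parameter was stored.
    """
    if result.draws is None or result.hq_draws is None:
        raise ValueError("rank_sensitivity needs a run with store_draws=True")
    varying = {k: v for k, v in result.draws.items() if np.ptp(v) > 0}
    if not varying:
        warnings.warn("no stochastic parameters; sensitivity is empty")
        return []
    out = []
    for name, v in varying.items():
        rho = stats.spearmanr(v, result.hq_draws).statistic
        out.append((name, float(rho)))
    out.sort(key=lambda t: abs(t[1]), reverse=True)
    return out


def mcspec_from_config(doc: Mapping, seed: int | None = None) -> MCSpec:
    """Build an :class:`MCSpec` from a loaded config dict's ``mc`` section."""
    mc = doc.get("mc") or {}
    dists = {}
    for name, d in (mc.get("distributions") or {}).items():
        dists[name] = DistributionSpec(
            kind=d["kind"],
            params=tuple(d["params"]),
            truncation=tuple(d["truncation"]) if d.get("truncation") else None,
        )
    spec = MCSpec(
        n_iter=int(mc.get("n_iter", 10_000)),
        seed=int(mc.get("seed", 0)),
        distributions=dists,
    )
    if seed is not None:
        spec = replace(spec, seed=seed)
    return spec
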