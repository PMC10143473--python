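# Methods

`soilcr` assesses total soil chromium contamination in industrial regions
from flat tables of literature-compiled measurements: one row per region
with a province, an industry-type code and a concentration `Cn` (mg/kg).
This note records the models, the defaults and the reasoning behind the
open design choices.

## Pollution indices

Two background-relative indices are computed per region, with the
background `Bn` resolved per province (national default 61 mg/kg):

* **Geoaccumulation (Muller) index** `I_geo = log2(Cn / (1.5 Bn))`. The
  1.5 factor absorbs natural lithogenic variability of the baseline.
  Classes follow the standard seven-level scheme: class 0 (`I_geo <= 0`,
  unpolluted) through class 6 (`I_geo > 5`, extremely polluted), interior
  classes on unit intervals `(k-1, k]`. Interior boundaries are
  upper-closed; `I_geo = 0` is class 0 and `I_geo = 5` class 5.
* **Hakanson monomial potential ecological risk** `E = Tn * Cn / Bn`, the
  contamination factor weighted by the toxic response coefficient
  (`Tn = 2` for Cr). Risk labels use the standard single-metal boundaries
  40 / 80 / 160 / 320, lower-closed (`E = 320` is already "significant
  high"). Both class tables are overridable.

The two indices satisfy `I_geo = log2(E / (1.5 Tn))` exactly; the test
suite asserts this identity to 1e-12 on random inputs as an internal
consistency check.

Exceedance statistics (background and the 2500 mg/kg industrial screening
value) use strict `>`. The standard deviation behind the coefficient of
variation uses the unbiased n-1 denominator; CV = 100·sd/mean. Percentages
are reported to two decimals. Zero or negative concentrations are rejected
at parse time because `I_geo` is undefined at 0; non-detect substitution
(e.g. half a detection limit) must happen upstream.

## Health-risk model

Non-carcinogenic exposure via three pathways (soil ingestion, dermal
contact, inhalation of resuspended particulates), using the standard
regulatory average-daily-dose forms given in the `health_risk` module
docstring. Each pathway's hazard quotient is `ADD/RfD`; the reported HQ is
the three-pathway sum (a single-metal hazard index), with HQ > 1 flagged.
A `pathways` switch restricts the sum (e.g. ingestion-only) for
sensitivity to the pathway set. Carcinogenic risk is out of scope: it
would require Cr(VI) speciation, which literature compilations of total Cr
cannot support.

Default receptor parameters are repository defaults assembled from the
USEPA Exposure Factors Handbook and Chinese HJ 25.3 conventions — child:
IngR 200 mg/day, BW 15 kg, ED 6 yr; adults: IngR 100 mg/day, BW 70/60 kg
(male/female), ED 24 yr; EF 350 d/yr, PEF 1.36e9 m³/kg, AT = ED·365 for
non-carcinogens. Reference doses default to oral 3e-3 mg/(kg·day) (the
Cr(VI) RfD, conservative for total Cr), dermal = oral × 2.5%
gastrointestinal absorption, inhalation 2.86e-5 mg/(kg·day) from the
Cr(VI) RfC. Every value is a config field; published HQ tables whose
exposure parameters differ can be reproduced by overriding them. With
these defaults child HQ exceeds both adult HQs at any concentration
(ingestion-to-body-weight ratio dominates), and female slightly exceeds
male (lower body weight).

## Monte Carlo uncertainty

Any receptor field or the concentration can be given a distribution
(point, uniform, normal, lognormal, triangular; optional truncation —
inverse-CDF restriction for normal/lognormal, capped rejection otherwise).
One seeded `numpy.random.Generator` stream per run, parameters drawn in
sorted-name order, so output is bit-reproducible from the seed and
independent of dict ordering or parallelism. Default 10,000 iterations.
Percentiles use the median-unbiased (Hyndman–Fan type 8) estimator; the
platform convention this emulates is unspecified in commercial MC tools,
so the choice is documented here and pinned by tests. Degenerate
(all-point-mass) runs reproduce the deterministic HQ exactly. Rank
sensitivity is Spearman correlation of each stored parameter sample
against the HQ sample, sorted by |rho|.

## Spatial aggregation and temporal trend

Regions map to six areas (Yangtze River Delta, Bohai Rim, Pearl River
Delta, Yangtze River Basin, Yellow River Basin, other) through a
province→area table. The shipped default uses standard provincial
membership (YRD: Shanghai/Jiangsu/Zhejiang/Anhui; Bohai Rim:
Beijing/Tianjin/Hebei/Shandong/Liaoning; PRD: Guangdong; basins by
standard membership); it is fully user-overridable, and a province listed
under several areas resolves to the highest-priority label (deltas/rim
before basins) with a warning. Per-area class distributions and
screening-exceedance shares sum to 1 (100%) before rounding.

The temporal trend is fitted to the yearly **median** concentration
(medians resist the extreme right skew; even-year medians average the two
middle values). Medians are log10-transformed and a quadratic in calendar
year is fitted by OLS — the minimal model with a single interior turning
point, matching the rise-then-fall these compilations show. Years are
centered before fitting to keep the normal equations well-conditioned,
then coefficients are de-centered. The vertex `-b/(2a)` is reported in
calendar years and omitted when `|a|` is numerically zero. `degree=3` and
`log_base=e` variants are available since neither the functional form nor
the log base is canonical.

## Synthetic data generator

No national compilation of this kind is publicly deposited, so the
generator emulates its statistical structure: within an industry type,
concentrations are lognormal (geometric mean `log_gm`, geometric SD
`log_gsd`); a quadratic year effect on the log10 median (normalised to 1
at its vertex) multiplies the median, so generator and trend-fit stage
share one model; provinces are drawn from fixed per-area lists.

`default_paperlike_spec` is calibrated to the qualitative features such
compilations exhibit at n ≈ 500:

* geometric means anchored so expected mean I_geo per type follows the
  characteristic ordering C (4.80) > T (4.08) > El (1.11) > E-w (0.30) >
  S (−0.24) > M (−0.73) against the 61 mg/kg national background
  (`gm = 1.5·61·2^target`), with the year effect's average folded back in
  so the anchors hold over the sampling window;
* type shares {M 0.34, S 0.24, E-w 0.14, El 0.115, T 0.065, C 0.10}:
  mining/smelting dominate counts, the high-concentration industries are
  rare but frequent enough that their mean ranks are resolvable from a
  single n=500 draw;
* geometric SDs {C 3.6, T 1.7, El 3.2, E-w 2.3, S 2.8, M 2.8}: the
  Cr-salt tail is heaviest and drives an overall CV of several hundred
  percent (median ≈ 400% at n=500), while tanning is tighter so the C/T
  mean ranks separate at a few dozen regions each;
* sampling years uniform on 2002–2021 with log10-median curvature
  −0.006 yr⁻² and vertex 2009, strong enough that the turning point is
  recovered within ±1.5 years from an n=2000 draw yet mild enough not to
  swamp the between-industry contrasts.

What the generator does **not** emulate: spatial correlation between
province and industry type, within-paper clustering of sampled regions,
year–industry interactions, censoring/detection limits, and any real
geographic gradient. Tests passing on synthetic tables therefore
demonstrate the correctness of the computational pipeline and the
recoverability of configured structure, not the field accuracy of any
specific published estimate.

## Problem sizes and numerics

The shipped tests use n=500–2000 region tables, 100-seed calibration
sweeps and 10,000 Monte Carlo iterations — the sizes the method itself
targets. Classification of NaN indices is a domain error, never silently
class 0. All index arithmetic is double precision via `math.log2`/numpy;
no extended precision is needed (verified against an arbitrary-precision
oracle to 1e-12). Empty groups (an industry type or area with no regions)
are omitted from summaries with a warning rather than reported as zeros.

## Known limitations

* Exposure-parameter defaults are repository conventions, not assertions
  about any specific published study; HQ magnitudes shift proportionally
  with the chosen RfDs.
* The quadratic trend is a descriptive fit; it has no mechanistic
  interpretation and extrapolates poorly outside the fitted window.
* Hotspot areas are provincial approximations; sub-provincial membership
  (e.g. a city on a basin boundary) is not resolved.
* Single-metal assessment only: no multi-metal composite indices.
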