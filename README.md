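# soilcr

Assessment toolkit for total soil chromium contamination in industrial
regions, built for literature-compiled tables: one row per region with a
province, an industry-type code (mining `M`, smelting `S`, e-waste `E-w`,
electroplating `El`, tanning `T`, chromium-salt production `C`), a
sampling year and a total Cr concentration `Cn` (mg/kg).

It computes, per region and in aggregate:

* **Geoaccumulation index** `I_geo = log2(Cn / (1.5 Bn))` with the
  standard 7-class scheme (class 0 unpolluted … class 6 extremely
  polluted, `I_geo > 5`), where `Bn` is the provincial soil Cr background
  (national default 61 mg/kg);
* **Potential ecological risk** `E = Tn · Cn / Bn` (Hakanson single-metal
  index, `Tn = 2` for Cr) with risk classes at 40/80/160/320;
* **Non-carcinogenic hazard quotients** for children, adult males and
  adult females via soil ingestion, dermal contact and particulate
  inhalation (`HQ = Σ ADD_pathway / RfD_pathway`, HQ > 1 flagged);
* **Monte Carlo uncertainty** on HQ (seeded, 10,000 iterations by
  default) with Spearman rank sensitivity;
* **Descriptive and exceedance statistics** (CV, share above background,
  share above the 2500 mg/kg industrial screening value);
* **Hotspot-area aggregation** over the Yangtze River Delta, Bohai Rim,
  Pearl River Delta, Yangtze River Basin and Yellow River Basin, and a
  **temporal trend** — OLS quadratic on log10 yearly median concentration
  with the turning-point year.

A seeded synthetic-data generator (`soilcr.synthetic_data`) emulates the
statistical structure of such compilations — strongly right-skewed
lognormal concentrations with industry-dependent levels, CV of several
hundred percent, and a rise-then-fall time trend peaking near 2009 — so
the whole pipeline is testable without any proprietary dataset. See
`docs/methods.md` for models, defaults and limitations.

## Worked example

```
soilcr generate --n-regions 506 --seed 42 --out regions.csv
soilcr report regions.csv --outdir run --seed 42
cat run/report.txt
```

```
Soil Cr assessment report
=========================
regions: 506
concentration range: 1.87 - 65217.57 mg/kg
mean 744.95 mg/kg, median 91.79 mg/kg, CV 516.61%
above background: 60.67%
above screening (2500 mg/kg): 5.53%

Per-industry-type indices:
  M    n= 175  mean I_geo   -1.06  mean E       2.98
  S    n= 113  mean I_geo   -0.50  mean E       3.98
  E-w  n=  78  mean I_geo   -0.32  mean E       3.85
  El   n=  67  mean I_geo    0.87  mean E      10.09
  T    n=  27  mean I_geo    3.99  mean E      68.34
  C    n=  46  mean I_geo    4.56  mean E     186.20
...
Temporal trend: vertex year 2008.1, r^2 0.746 (20 years)
```

Reading this: the synthetic compilation is extremely dispersed (CV ≈
517%, mean eight times the median — a handful of very contaminated sites
dominate). Chromium-salt production and tanning regions average I_geo ≈
4–4.6 ("heavily to extremely polluted") and carry high ecological risk,
while mining areas sit below background (negative I_geo). The fitted
log-median trend peaks in 2008, i.e. concentrations rose and then
declined across 2002–2021. The run directory also contains per-region
index and health-risk CSVs, a Monte Carlo summary, the trend fit as JSON
and a manifest.

The same operations are available as a library:

```python
from soilcr import BackgroundTable, igeo, ecological_risk, classify_igeo

igeo(2500, 61)            # 4.772
ecological_risk(2500, 61) # 81.967
classify_igeo(5.1)        # 6  (extremely polluted)
```

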