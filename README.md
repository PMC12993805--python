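# peatfire

Statistical synthesis of macroscopic-charcoal records from tropical peatlands:
a reusable pipeline for reconstructing regional burning histories over the
last two millennia and asking whether the 20th century burned differently.

Charcoal counted in dated peat cores is the standard proxy for past local
fire. Comparing many cores is hard: laboratories report different units,
records are skewed and full of zeros (peat fires are infrequent), sampling
resolution is irregular, and every chronology carries its own uncertainty.
`peatfire` implements the full chain a regional synthesis needs, plus a
synthetic-data generator with known fire-regime truth so every stage can be
validated end-to-end:

- **Monte-Carlo age–depth models** — piecewise-linear chronologies sampled
  from calendar-age controls (`Normal(age, σ)`, rejection-sampled to remain
  stratigraphically ordered), with the quality-control rule that a core needs
  at least two age controls within the last 3000 years.
- **Influx and PRS transform** — concentrations (particles cm⁻³) become
  influx (particles cm⁻² yr⁻¹) via the accumulation rate, then each record is
  rescaled to 0–100 by *proportional relative scaling*:

  `Char_PRS,i = (C_i / C_max) × 100 × (f / N)`

  where `C_max` is the record maximum and `f/N` the fraction of positive
  samples — a transform built for sparsely recorded, zero-inflated series.
- **Regional composite curves** — 25-yr binning over 0–2000 CE, a 200-yr
  tricube locally weighted smoother, and a 5–95% confidence band from 1000
  bootstrap resamples of sites.
- **Change-point detection** — "at most one change" in mean and variance
  under a Gaussian likelihood with an MBIC-style penalty, run on the
  composite curves.
- **20th-century change map** — per-site contrast of mean PRS in 1900–2000 CE
  against 0–1900 CE, classified into the eight ordered signal classes from
  "extremely strong positive" (Δ > 50) to "strong negative" (−50 ≤ Δ < −15).
- **Site-level statistics** — Kruskal-Wallis and one-way ANOVA across
  regions, ecosystem types, elevation groups and human-footprint classes;
  PCA over climate covariates; correlation-screened multiple regression with
  backward selection.

## Worked example

Generate a 58-site synthetic compilation (16 Neotropical, 15 Afrotropical,
16 Indomalayan, 8 Australasian, 3 Oceanian sites; the Indomalayan and
Australasian regimes carry a ×5 burning increase at 1900 CE, the Neotropical
and Afrotropical a ×0.5 decrease) and run the full synthesis:

```python
import peatfire as pf
from collections import Counter

recs, series, controls, truths, sites = pf.compilation_preset(seed=7)
cfg = pf.PipelineConfig(seed=7, group_by=("region",))
res = pf.run_pipeline(cfg, recs, series, controls)

for label, cp in sorted(res.changepoints.items()):
    print(f"{label:24s} tau_year={cp.tau_year:7.1f} "
          f"statistic={cp.statistic:6.1f} significant={cp.significant}")
kw = res.stats["group_tests"]["region_20c_delta"]["kruskal_wallis"]
print("classes:", dict(Counter(s.signal_class for s in res.signals.values())))
print("Kruskal-Wallis on 20th-century deltas: H=%.2f p=%.2e" % (kw["H"], kw["p"]))
```

prints

```
all:tropics              tau_year= 1862.5 statistic= 141.0 significant=True
region:Afrotropical      tau_year=  287.5 statistic=  21.7 significant=True
region:Australasian      tau_year= 1887.5 statistic= 146.8 significant=True
region:Indomalayan       tau_year= 1862.5 statistic= 213.6 significant=True
region:Neotropical       tau_year=  412.5 statistic=  15.1 significant=False
region:Oceanian          tau_year=  412.5 statistic=   9.1 significant=False
classes: {'negative': 10, 'strong positive': 16, 'weak negative': 17,
          'weak positive': 7, 'positive': 8}
Kruskal-Wallis on 20th-century deltas: H=37.17 p=1.66e-07
```

The two regions carrying the injected ×5 break are flagged with significant
change-points within one smoothing bandwidth of 1900 CE; their sites dominate
the positive signal classes; and the rank test cleanly separates the regional
20th-century deltas. The Afrotropical curve's significant change-point at
~290 CE is a reminder that a single-change detector reports the globally best
split, not necessarily the most recent one.

The same pipeline runs from the shell:

```bash
peatfire synth --n-sites 58 --seed 7 --out-dir data/
peatfire validate data/
peatfire run --in data/ --out results/ --seed 7
```

Real compilations are supplied as three CSV tables (`sites.csv`,
`charcoal.csv`, `age_controls.csv`; see `peatfire.record_io` for the column
schemas) with already-calibrated calendar ages.

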