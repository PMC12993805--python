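# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions that matter for reproducing
results.

## Scope and data model

The pipeline synthesises many single-site charcoal records into regional
burning histories over the window 0–2000 CE. A site contributes three
tables: metadata (location, realm, ecosystem, elevation, human-footprint
index, organic-matter/carbon content), a depth-ordered charcoal series in
either concentration (particles cm⁻³) or influx (particles cm⁻² yr⁻¹)
units, and calendar-age control points (core top, calibrated radiocarbon,
²¹⁰Pb/¹³⁷Cs) with 1σ uncertainties. Radiocarbon calibration is outside the
package's scope: ages are accepted already in calendar years CE. Site
inclusion applies, in order, a tropics rule (|lat| ≤ 30°, closed interval,
with an explicit allowlist for near-boundary sites retained by judgement), a
peat criterion (≥ 30% organic matter, or ≥ 15% carbon, or — when neither
measurement exists — the source publication's description), and a chronology
quality-control rule (at least two age controls within the last 3000 years,
so the last two millennia are interpolated, never extrapolated). Continuous
minerogenic sections are excluded through an optional per-site depth mask
supplied in the site table, not inferred from geochemistry.

## Age–depth models

Chronologies are Monte-Carlo piecewise-linear: each ensemble draw samples
every control age from Normal(age, σ) and is kept only if ages remain
strictly ordered with depth; a draw failing 1000 resampling attempts is
sorted into order and flagged. Depths between controls are linearly
interpolated. This deliberately replaces fully Bayesian accumulation-rate
models: everything downstream needs only dated samples and per-segment
accumulation rates, and the ensemble already propagates the dominant
uncertainty (control ages) into both. The number of draws (default 500) only
affects the smoothness of the ensemble quantiles.

Two conventions: samples are dated by the *median* chronology, so each site
contributes a single dated series to composites (which point estimate of an
age model feeds the influx calculation is a genuinely open choice; the
median is ours), and the accumulation rate at a depth is the median across
draws of the segment quotient Δdepth/Δage, with a depth exactly at an
interior control belonging to the segment above it. As all control σ → 0 the
ensemble collapses to deterministic linear interpolation (tested to 1e-9).

## Influx and proportional relative scaling

Concentration samples are dated and converted at their interval midpoints:
influx = concentration × accumulation rate. The PRS transform then maps a
whole record to a common 0–100 scale,

    Char_PRS,i = (C_i / C_max) · 100 · (f / N),

with `f` the number of positive samples and `N` the record length. The
transform is exactly scale-invariant (laboratory units cancel), zeros map to
zeros, and the record maximum maps to 100·f/N — so a record dominated by
zeros can never dominate a composite. `f` and `N` are computed over the full
record before any windowing or binning (whether they should instead be
computed over 0–2000 CE only is unstated in the methods this follows; the
full record is our default and a configuration switch). Samples equal to
`C_max` all map to 100·f/N; no tie-breaking is needed.

## Composite curves

Per site, PRS values are averaged into non-overlapping 25-yr bins on
[0, 2000) CE (origin 0 CE, last bin [1975, 2000); empty bins are missing
data, never zero). The cross-site per-bin mean is smoothed by tricube-
weighted local *linear* regression with a fixed metric half-window of 100 yr
(a "200-yr window"). The smoother reproduces constants and straight lines
exactly, and because the bin grid is fixed it is a linear operator — a
precomputed matrix — which makes the bootstrap cheap. Bins with no
contributing site are skipped as smoothing targets rather than interpolated.
Confidence bands resample *sites* with replacement (records are the
exchangeable unit, not samples within records) 1000 times, recompute and
smooth the per-bin means, and take the 5th/95th percentiles per target.
Sites are sorted by identifier before resampling, so the composite is
invariant to input order at a fixed seed. On homogeneous 20-site groups the
band covers the true smoothed mean curve at ~87% of targets (nominal 90%;
percentile bootstrap under-covers slightly at n = 20).

Landscape (non-peat) comparison records are selected by great-circle
distance (haversine, R = 6371 km): a candidate is retained if it lies within
800 km of at least one peat site.

## Change-point detection

Composite mean curves are tested for a single simultaneous change in mean
and variance ("at most one change"). The Gaussian segment cost is
n·log(σ̂²_MLE); the statistic is the likelihood-ratio gain of the best
admissible split (both segments ≥ 2 points), compared against an MBIC-style
penalty 4·log(n). Conventions: segment variances are computed by the exact
two-pass formula (a constant segment has variance exactly zero, then floored
at 1e-12 to keep the log finite and flagged); ties break toward the smallest
split; the statistic is invariant to adding a constant. `tau_index` is the
length of the first segment; `tau_year` is reported at the first smoothed
target of the *second* segment — the year the new regime takes effect. The
distinction matters because 200-yr smoothing turns a step into a ramp whose
onset precedes the true break by up to one bandwidth; reporting the start of
the second segment keeps detected years centred on the true change (a ×5
step at 1900 CE is located within 1850–1950 CE in ≥ 90% of noisy-composite
simulations). On an 80-point Gaussian series with a 2σ midpoint mean shift
the detector is significant with |τ̂ − 40| ≤ 3 in ~97% of runs, with a ~2%
false-positive rate on pure noise.

A one-change detector reports the globally best split. On curves whose
largest feature is early (e.g., elevated burning in the first millennium)
the detected year describes that feature, not the 20th century — seen both
on synthetic Afrotropical curves and in real tropical syntheses.

## 20th-century change map

Per site, delta = mean PRS over 1900–2000 CE (inclusive) minus mean PRS over
[0, 1900) CE, both over raw samples (not bins; a configuration switch
exposes the alternative); relative change divides delta by the 0–2000 CE
mean and is undefined (NaN) for all-zero records. Sites lacking samples in
either window are excluded from the map with a logged reason — with
~25-yr-resolution records a meaningful share of sites has no 20th-century
sample, mirroring real compilations. Deltas map to eight ordered signal
classes (>50 extremely strong positive; 15–50 strong positive; 5–15
positive; 0–5 weak positive; exactly 0 no change; −5–0 weak negative;
−15–−5 negative; −50–−15 strong negative). The published table is ambiguous
at the shared boundaries; we close each interval on the side away from zero
(so Δ = 15 is "positive", Δ = −15 "negative") and keep the whole convention
in one table so an alternative is a one-line change. Deltas below −50 get a
mirrored "extremely strong negative" class, flagged as an extension rather
than clamped.

## Site-level statistics

Burning status per site is the median PRS over the analysis window,
cube-root transformed toward normality. Groupings: realm; ecosystem type
(cushion/sedge, hardwood swamp, palm swamp, other); elevation (lowland
< 500 m, upland 500–1500 m boundaries included, highland > 1500 m a.s.l.);
human footprint on the 0–50 index (wilderness < 1, intact 1–4 inclusive,
highly modified > 4). Kruskal-Wallis uses mid-ranks with tie correction and
a χ² reference on k−1 df; one-way ANOVA is the classical between/within
mean-square ratio with F = ∞ (p = 0) when within-group variance vanishes
with unequal means. Both match scipy.stats to 1e-8. PCA standardises the
covariates and eigendecomposes the correlation matrix, ordering components
by eigenvalue and signing each so its largest-magnitude loading is positive.
The regression chain keeps covariates with |Pearson r| > 0.25 against the
response (0.3 is the alternative pre-selection screen; both exposed), drops
the weaker member of any pair with mutual |r| > 0.8, then fits OLS with
backward elimination until every term has p < 0.05. An empty surviving set
is a reported outcome, not an error. p-values are reported as-is, with no
multiple-testing adjustment. Climate covariates are input columns; no
climate-grid retrieval is performed, and mixed-effects variants are out of
scope.

## Synthetic-data generator

The generator exists so that every downstream stage can be tested against
known truth. It emulates the *structure* of a tropical peat-charcoal
compilation: ~58 sites split 16/15/16/8/3 across the Neotropical,
Afrotropical, Indomalayan, Australasian and Oceanian realms; skewed,
zero-inflated influx; irregular resolution with median bin duration near
25 yr; 4–10 age controls per core with 20–60 yr uncertainties (the core top
is the collection year, known to ~2 yr); and region-specific 20th-century
regime shifts — a ×5 step at 1900 CE in Indomalaya/Australasia, ×0.5 in the
Neotropics/Afrotropics, none in Oceania.

Influx is log-normal (baseline log-sd 0.8) times step/trend multipliers,
with Poisson fire-event pulses (1.5 kyr⁻¹, each multiplying one sample by 4)
and Bernoulli zero-inflation (probability 0.25) applied last. These levels
keep records strongly skewed and zero-rich while leaving an injected regime
shift as the dominant low-frequency feature of a composite — matching
reconstructions in which the 20th-century rise dominates the affected
regions' curves. At substantially heavier pulse regimes the one-change
detector increasingly reports pre-1900 excursions on small (8-site) groups;
that regime describes a harder inference problem, not a different pipeline.
The true chronology is piecewise-linear with per-segment rates drawn
log-normally around 0.05 cm yr⁻¹ and rescaled downward when a core with ≥ 2
controls would span less than 3000 yr, so every preset core passes
chronology QC. Concentration = influx / true rate, so charcoal mass is
conserved exactly between truth and observation; observed control ages add
Gaussian noise to the true ages.

Not emulated: taphonomy and charcoal transport, sediment compaction and
age-dependent accumulation trends, hiatuses, analyst-dependent counting
error, and spatial correlation between nearby sites. Passing tests
demonstrate that the pipeline recovers regimes *of the generated kind*; they
do not certify behaviour on records whose noise violates these assumptions.

## Reproducibility and problem sizes

All randomness flows from integer seeds through named generator streams
(per-site streams are derived from a hash of the site identifier, so results
do not depend on site order). Re-running the pipeline with the same
configuration and seed reproduces outputs byte-for-byte. Default problem
sizes — 58 sites, 500 age-model draws, 1000 bootstrap replicates, and
100-seed simulation batches in the acceptance suite — keep a full run in
seconds and the complete test suite in a few minutes while leaving
Monte-Carlo error well inside the tolerances asserted.

## Known limitations

- The one-change detector cannot represent multiple regime shifts; curves
  with several features report only the globally dominant one.
- Percentile bootstrap bands under-cover slightly for small groups; bands
  for 8-site regions should be read indicatively.
- The PRS transform ties every value to the record maximum: a single
  extreme sample rescales the whole record, which is the transform's
  intended robustness-for-comparability trade-off.
- Numeric identity with published composite curves from other software is
  not claimed: the exact pretreatment inside other compositing packages is
  not documented, and the smoother here is defined independently
  (tricube-weighted local linear regression, fixed metric window).
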