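"""Synthetic tropical peatland charcoal records with known fire-regime truth.

The generator emulates the structure of a multi-site tropical peat charcoal
compilation: ~50–60 sites spread over the Neotropical, Afrotropical,
Indomalayan, Australasian and Oceanian realms; skewed, zero-inflated charcoal
influx; irregular sampling resolution (median bin near 25 yr); 2–15
calendar-age controls per core; and region-specific 20th-century regime
shifts (burning increase in Indomalaya/Australasia, decrease in the
Neotropics/Afrotropics).

Influx model: log-normal baseline × step/trend multipliers × Poisson-count
pulse events (each pulse multiplies one sample by ``pulse_scale``); zeros are
applied last by a Bernoulli mask. The true chronology is piecewise-linear
with log-normally drawn per-segment accumulation rates (mean 0.05 cm/yr),
stretched when needed so every core with ≥ 2 controls spans at least the last
3000 years; observed control ages are the true ages plus Gaussian noise.
Concentration = influx / true accumulation rate, so charcoal mass is
conserved exactly between the influx truth and the concentration record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .record_io import (
    CONCENTRATION,
    AgeControlSet,
    CharcoalSeries,
    SiteRecord,
    write_tables,
)

__all__ = [
    "RegimeSpec",
    "SyntheticSite",
    "CoreTruth",
    "REGION_CODES",
    "REGION_REGIMES",
    "generate_site_set",
    "generate_core",
    "compilation_preset",
    "write_synthetic_dataset",
]

COLLECTION_YEAR_CE = 2000.0
TOP_CONTROL_SD_YR = 2.0
MIN_SPAN_YR = 3000.0
DEFAULT_ACCUMULATION_CM_YR = 0.05

REGION_CODES = {
    "Neotropical": "NT",
    "Afrotropical": "AT",
    "Indomalayan": "IM",
    "Australasian": "AA",
    "Oceanian": "OC",
}
_CODE_TO_REGION = {v: k for k, v in REGION_CODES.items()}

# Rough tropical bounding boxes per realm (deg): lat_min, lat_max, lon_min, lon_max
_REGION_BOX = {
    "Neotropical": (-25.0, 10.0, -85.0, -40.0),
    "Afrotropical": (-20.0, 10.0, 8.0, 40.0),
    "Indomalayan": (-8.0, 25.0, 70.0, 120.0),
    "Australasian": (-25.0, 0.0, 110.0, 155.0),
    "Oceanian": (-20.0, 0.0, 155.0, 179.0),
}

_REGION_ECOSYSTEMS = {
    "Neotropical": (("palm_swamp", 0.4), ("cushion_sedge", 0.3), ("hardwood_swamp", 0.2), ("other", 0.1)),
    "Afrotropical": (("palm_swamp", 0.3), ("cushion_sedge", 0.2), ("hardwood_swamp", 0.3), ("other", 0.2)),
    "Indomalayan": (("hardwood_swamp", 0.7), ("palm_swamp", 0.1), ("cushion_sedge", 0.0), ("other", 0.2)),
    "Australasian": (("hardwood_swamp", 0.5), ("cushion_sedge", 0.2), ("palm_swamp", 0.1), ("other", 0.2)),
    "Oceanian": (("hardwood_swamp", 0.4), ("cushion_sedge", 0.2), ("palm_swamp", 0.2), ("other", 0.2)),
}


@dataclass(frozen=True)
class RegimeSpec:
    """Parameters of one site's generative fire regime.

    baseline_log_mean/baseline_log_sd: log influx level and noise
    (log particles cm^-2 yr^-1); zero_prob: probability a sample records no
    charcoal; event_rate: fire-event pulses per kyr; pulse_scale:
    multiplicative pulse magnitude; breaks: (year CE, multiplier) step
    changes applied to samples younger than the break year; trend:
    linear multiplier per century, applied as (1 + trend·(age − 0 CE)/100).
    """

    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 0.8
    zero_prob: float = 0.25
    event_rate: float = 1.5
    pulse_scale: float = 4.0
    breaks: tuple[tuple[float, float], ...] = ()
    trend: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.zero_prob <= 1.0:
            raise ValueError("zero_prob must be in [0, 1]")
        if self.event_rate < 0:
            raise ValueError("event_rate must be >= 0")
        if self.pulse_scale <= 0:
            raise ValueError("pulse_scale must be > 0")
        for year, mult in self.breaks:
            if mult <= 0:
                raise ValueError(f"break multiplier at {year} CE must be > 0")


#: Region-default regimes: a positive 20th-century break in Indomalaya and
#: Australasia, a negative one in the Neotropics and Afrotropics, none in
#: Oceania.
REGION_REGIMES: dict[str, RegimeSpec] = {
    "Neotropical": RegimeSpec(breaks=((1900.0, 0.5),)),
    "Afrotropical": RegimeSpec(breaks=((1900.0, 0.5),)),
    "Indomalayan": RegimeSpec(breaks=((1900.0, 5.0),)),
    "Australasian": RegimeSpec(breaks=((1900.0, 5.0),)),
    "Oceanian": RegimeSpec(),
}


@dataclass(frozen=True)
class SyntheticSite:
    """One simulated peatland site and its generative regime."""

    site_id: str
    region: str
    ecosystem: str
    lat: float
    lon: float
    elevation_m: float
    footprint: float
    regime: RegimeSpec
    true_change_year: float | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError("lat outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError("lon outside [-180, 180]")
        if self.elevation_m < 0:
            raise ValueError("elevation must be >= 0")

    def to_site_record(self, om_pct: float = 60.0) -> SiteRecord:
        return SiteRecord(
            site_id=self.site_id,
            region=self.region,
            ecosystem=self.ecosystem,
            lat=self.lat,
            lon=self.lon,
            elevation_m=self.elevation_m,
            footprint=self.footprint,
            om_pct=om_pct,
            c_pct=None,
            is_peat=True,
        )


@dataclass
class CoreTruth:
    """Noise-free generative truth for one core, kept for ground-truth tests."""

    site_id: str
    mid_depth_cm: np.ndarray
    true_age_ce: np.ndarray
    true_influx: np.ndarray
    true_rate_cm_yr: np.ndarray
    ctrl_depth_cm: np.ndarray
    ctrl_true_age_ce: np.ndarray
    true_change_year: float | None
    regime: RegimeSpec


def _largest_remainder_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    labels = list(proportions)
    for lab in labels:
        if proportions[lab] < 0:
            raise ValueError(f"region proportion for {lab!r} is negative")
    total = sum(proportions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(
            f"region proportions must sum to 1 (got {total:.12g}; labels {labels})"
        )
    raw = {lab: n * proportions[lab] for lab in labels}
    counts = {lab: int(math.floor(raw[lab])) for lab in labels}
    remainder = n - sum(counts.values())
    by_frac = sorted(labels, key=lambda lab: (-(raw[lab] - counts[lab]), lab))
    for lab in by_frac[:remainder]:
        counts[lab] += 1
    return counts


def generate_site_set(
    n_sites: int,
    region_mix: dict[str, float],
    seed: int,
    regimes: dict[str, RegimeSpec] | None = None,
) -> list[SyntheticSite]:
    """Generate a deterministic set of synthetic sites.

    Region counts follow largest-remainder rounding of *region_mix* (keys may
    be full realm names or the two-letter codes). Each site draws its
    location, ecosystem, elevation and footprint from region-specific
    distributions and carries the region's default RegimeSpec (overridable
    via *regimes*), with a per-site jitter on the baseline log level.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    mix = {}
    for lab, p in region_mix.items():
        region = _CODE_TO_REGION.get(lab, lab)
        if region not in REGION_CODES:
            raise ValueError(f"unknown region label {lab!r}")
        mix[region] = mix.get(region, 0.0) + p
    counts = _largest_remainder_counts(n_sites, mix)
    regimes = {**REGION_REGIMES, **(regimes or {})}

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_sites)
    sites: list[SyntheticSite] = []
    i = 0
    for region in REGION_CODES:  # fixed realm order for determinism
        if region not in counts:
            continue
        code = REGION_CODES[region]
        for k in range(counts[region]):
            rng = np.random.default_rng(children[i])
            lat0, lat1, lon0, lon1 = _REGION_BOX[region]
            eco_labels, eco_p = zip(*_REGION_ECOSYSTEMS[region])
            eco_p = np.asarray(eco_p) / np.sum(eco_p)
            ecosystem = str(rng.choice(eco_labels, p=eco_p))
            if ecosystem == "cushion_sedge":
                elevation = float(rng.uniform(2000.0, 4500.0))
            else:
                elevation = float(rng.uniform(0.0, 400.0))
            base = regimes[region]
            regime = replace(
                base,
                baseline_log_mean=base.baseline_log_mean + float(rng.normal(0.0, 0.5)),
                zero_prob=float(np.clip(rng.normal(base.zero_prob, 0.08), 0.0, 0.9)),
            )
            sites.append(
                SyntheticSite(
                    site_id=f"{code}{k + 1:02d}",
                    region=region,
                    ecosystem=ecosystem,
                    lat=float(rng.uniform(lat0, lat1)),
                    lon=float(rng.uniform(lon0, lon1)),
                    elevation_m=elevation,
                    footprint=float(np.clip(rng.gamma(2.0, 2.0), 0.0, 50.0)),
                    regime=regime,
                    true_change_year=base.breaks[0][0] if base.breaks else None,
                )
            )
            i += 1
    return sites


def _true_chronology(
    depth_cm: float,
    n_age_controls: int,
    rng: np.random.Generator,
    collection_year: float = COLLECTION_YEAR_CE,
    min_span_yr: float = MIN_SPAN_YR,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Piecewise-linear true chronology.

    Returns (control_depths, true_control_ages_ce, segment_rates_cm_yr).
    Segment rates are log-normal around the default 0.05 cm/yr; when a core
    with >= 2 controls would span less than *min_span_yr*, all rates are
    rescaled downward so the span is exactly *min_span_yr*.
    """
    n_seg = max(n_age_controls - 1, 1)
    depths = np.linspace(0.0, depth_cm, max(n_age_controls, 2))
    rates = rng.lognormal(np.log(DEFAULT_ACCUMULATION_CM_YR), 0.3, size=n_seg)
    durations = np.diff(depths) / rates
    span = durations.sum()
    if n_age_controls >= 2 and span < min_span_yr:
        rates = rates * (span / min_span_yr)
        durations = np.diff(depths) / rates
    ages = collection_year - np.concatenate([[0.0], np.cumsum(durations)])
    return depths, ages, rates


def generate_core(
    site: SyntheticSite,
    depth_cm: float,
    sample_step_cm: float,
    n_age_controls: int,
    age_sd_yr: float,
    seed: int | np.random.SeedSequence,
) -> tuple[AgeControlSet, CharcoalSeries, CoreTruth]:
    """Simulate one core: age controls, concentration series and truth.

    Samples are contiguous *sample_step_cm*-thick intervals dated (in truth)
    at their midpoints; age controls sit at evenly spaced depths including
    the core top (collection year) and carry Gaussian observation noise of
    sd *age_sd_yr*.
    """
    if depth_cm <= 0 or sample_step_cm <= 0:
        raise ValueError("core geometry must be positive")
    if n_age_controls < 1:
        raise ValueError("need at least 1 age control")
    rng = np.random.default_rng(seed)
    regime = site.regime

    ctrl_depths, ctrl_ages, seg_rates = _true_chronology(depth_cm, n_age_controls, rng)

    n = int(math.floor(depth_cm / sample_step_cm))
    tops = sample_step_cm * np.arange(n)
    mids = tops + 0.5 * sample_step_cm
    true_age = np.interp(mids, ctrl_depths, ctrl_ages)
    seg = np.clip(np.searchsorted(ctrl_depths, mids, side="right") - 1, 0, len(seg_rates) - 1)
    rate = seg_rates[seg]

    influx = np.exp(rng.normal(regime.baseline_log_mean, regime.baseline_log_sd, size=n))
    for year, mult in regime.breaks:
        influx[true_age >= year] *= mult
    if regime.trend != 0.0:
        influx *= np.clip(1.0 + regime.trend * (true_age / 100.0), 1e-12, None)
    span_kyr = (true_age.max() - true_age.min()) / 1000.0
    n_pulses = int(rng.poisson(regime.event_rate * span_kyr))
    if n_pulses > 0:
        hit = rng.integers(0, n, size=n_pulses)
        for h in hit:
            influx[h] *= regime.pulse_scale
    zero_mask = rng.random(n) < regime.zero_prob
    influx[zero_mask] = 0.0

    concentration = influx / rate

    # the core top is dated by the collection year itself: essentially exact,
    # unlike the interior (radiometric) controls
    sds = np.full(len(ctrl_depths), float(age_sd_yr))
    sds[0] = TOP_CONTROL_SD_YR
    obs_ages = ctrl_ages + rng.normal(0.0, sds)
    controls = AgeControlSet(
        site_id=site.site_id,
        depth_cm=ctrl_depths,
        age_ce=obs_ages,
        sd_yr=sds,
    )
    series = CharcoalSeries(
        site_id=site.site_id,
        depth_top_cm=tops,
        depth_bottom_cm=tops + sample_step_cm,
        value=concentration,
        unit=CONCENTRATION,
    )
    truth = CoreTruth(
        site_id=site.site_id,
        mid_depth_cm=mids,
        true_age_ce=true_age,
        true_influx=influx,
        true_rate_cm_yr=rate,
        ctrl_depth_cm=ctrl_depths,
        ctrl_true_age_ce=ctrl_ages,
        true_change_year=site.true_change_year,
        regime=regime,
    )
    return controls, series, truth


#: Region mix matching a 16/15/16/8/3-site compilation across the five realms.
COMPILATION_MIX = {
    "Neotropical": 16 / 58,
    "Afrotropical": 15 / 58,
    "Indomalayan": 16 / 58,
    "Australasian": 8 / 58,
    "Oceanian": 3 / 58,
}


def compilation_preset(
    seed: int,
    n_sites: int = 58,
    regimes: dict[str, RegimeSpec] | None = None,
) -> tuple[list[SiteRecord], dict[str, CharcoalSeries], dict[str, AgeControlSet], dict[str, CoreTruth], list[SyntheticSite]]:
    """Standard synthetic compilation: 58 sites in a 16/15/16/8/3 realm
    split, core depths 120–250 cm, 4–10 age controls, 1–2 cm sampling,
    age-control sd 20–60 yr.

    Every core passes the chronology QC rule by construction (the true span
    is stretched to >= 3000 yr and controls are dense enough that at least
    two fall in the last 3000 years).
    """
    sites = generate_site_set(n_sites, COMPILATION_MIX, seed=seed, regimes=regimes)
    ss = np.random.SeedSequence((seed, 2**20))
    children = ss.spawn(len(sites))
    site_records: list[SiteRecord] = []
    series: dict[str, CharcoalSeries] = {}
    controls: dict[str, AgeControlSet] = {}
    truths: dict[str, CoreTruth] = {}
    for site, child in zip(sites, children):
        rng = np.random.default_rng(child.spawn(1)[0])
        depth = float(rng.uniform(120.0, 250.0))
        step = float(rng.choice([1.0, 1.5, 2.0]))
        n_ctrl = int(rng.integers(4, 11))
        age_sd = float(rng.uniform(20.0, 60.0))
        ctrl, ser, truth = generate_core(site, depth, step, n_ctrl, age_sd, child)
        site_records.append(site.to_site_record(om_pct=float(rng.uniform(35.0, 95.0))))
        series[site.site_id] = ser
        controls[site.site_id] = ctrl
        truths[site.site_id] = truth
    return site_records, series, controls, truths, sites


def write_synthetic_dataset(
    out_dir,
    seed: int,
    n_sites: int = 58,
    regimes: dict[str, RegimeSpec] | None = None,
) -> dict[str, str]:
    """Write the compilation preset as the three interchange tables plus a
    truth table (site_id, region, true_change_year, regime parameters)."""
    site_records, series, controls, truths, sites = compilation_preset(
        seed, n_sites=n_sites, regimes=regimes
    )
    paths = write_tables(out_dir, site_records, series, controls)
    truth_df = pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "region": [s.region for s in sites],
            "true_change_year": [s.true_change_year for s in sites],
            "baseline_log_mean": [s.regime.baseline_log_mean for s in sites],
            "baseline_log_sd": [s.regime.baseline_log_sd for s in sites],
            "zero_prob": [s.regime.zero_prob for s in sites],
            "event_rate": [s.regime.event_rate for s in sites],
            "pulse_scale": [s.regime.pulse_scale for s in sites],
            "break_multiplier": [
                s.regime.breaks[0][1] if s.regime.breaks else None for s in sites
            ],
        }
    )
    truth_path = str(Path(out_dir) / "truth.csv")
    truth_df.to_csv(truth_path, index=False)
    paths["truth"] = truth_path
    return paths
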