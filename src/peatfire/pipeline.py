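"""End-to-end orchestration: ingest → inclusion rules → chronology QC →
age models → influx → PRS → composites → change points → change map → stats.

Every stage is a thin call into the corresponding module; the pipeline adds
site-inclusion accounting (tropics rule, peat criterion, chronology QC,
missing-window exclusions), deterministic per-site seeding, and CSV/JSON
output with a run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import age_depth, change_map, changepoint, composite, record_io, site_stats, transform

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable parameters, defaulting to the study's stated settings."""

    bin_width: float = 25.0
    smooth_window: float = 200.0
    bootstrap_reps: int = 1000
    percentiles: tuple[float, float] = (5.0, 95.0)
    buffer_km: float = 800.0
    window_start_ce: float = 0.0
    window_end_ce: float = 2000.0
    periods: tuple[tuple[float, float], ...] = ((0.0, 850.0), (850.0, 1900.0), (1900.0, 2000.0))
    recent_window: tuple[float, float] = (1900.0, 2000.0)
    qc_window_start_ce: float = -1000.0
    n_age_draws: int = 500
    seed: int = 0
    tropics_allowlist: tuple[str, ...] = ()
    r_threshold: float = 0.25
    collinearity_threshold: float = 0.8
    penalty: str | float = "MBIC"
    group_by: tuple[str, ...] = ("region", "ecosystem")
    min_group_sites: int = 2

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["percentiles"] = list(self.percentiles)
        d["periods"] = [list(p) for p in self.periods]
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Load a YAML config; absent keys keep their defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig()
    for key, value in raw.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown config key {key!r}")
        default = getattr(cfg, key)
        if isinstance(default, tuple) and value is not None:
            value = tuple(tuple(v) if isinstance(v, (list, tuple)) else v for v in value)
        setattr(cfg, key, value)
    return cfg


@dataclass
class PipelineResult:
    """In-memory bundle of everything the pipeline produced."""

    config: PipelineConfig
    included: list[str]
    excluded: dict[str, str]
    ensembles: dict[str, age_depth.AgeModelEnsemble]
    prs: dict[str, transform.PRSSeries]
    composites: dict[str, composite.CompositeCurve]
    changepoints: dict[str, changepoint.ChangePointResult]
    signals: dict[str, change_map.ChangeSignal]
    signal_excluded: dict[str, str]
    stats: dict
    manifest: dict = field(default_factory=dict)


def _site_seed(base_seed: int, site_id: str) -> np.random.SeedSequence:
    h = int.from_bytes(hashlib.sha256(site_id.encode()).digest()[:4], "big")
    return np.random.SeedSequence((base_seed, h))


def run_pipeline(
    config: PipelineConfig,
    sites: list[record_io.SiteRecord],
    series: dict[str, record_io.CharcoalSeries],
    controls: dict[str, record_io.AgeControlSet],
    out_dir: str | Path | None = None,
    covariates: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run the full synthesis on already-loaded tables.

    Site inclusion applies, in order: tropics rule, peat criterion,
    chronology QC (>= 2 controls in the last 3000 yr). Sites lacking samples
    in either contrast window are excluded from the change map only (with a
    logged reason), matching the study's reduced change-map site count.
    """
    allow = frozenset(config.tropics_allowlist)
    included: list[str] = []
    excluded: dict[str, str] = {}
    site_by_id = {s.site_id: s for s in sites}

    for site in sites:
        if not record_io.in_tropics(site, allow):
            excluded[site.site_id] = f"outside tropics (lat {site.lat:g})"
            continue
        ok, reason = record_io.passes_peat_criterion(site)
        if not ok:
            excluded[site.site_id] = f"peat criterion failed: {reason}"
            continue
        if site.site_id not in series or site.site_id not in controls:
            excluded[site.site_id] = "missing charcoal series or age controls"
            continue
        if not age_depth.passes_chronology_qc(
            controls[site.site_id], config.qc_window_start_ce
        ):
            excluded[site.site_id] = (
                "chronology QC failed: fewer than 2 age controls in the last 3000 years"
            )
            continue
        included.append(site.site_id)

    # chronologies and transforms
    ensembles: dict[str, age_depth.AgeModelEnsemble] = {}
    prs: dict[str, transform.PRSSeries] = {}
    for sid in list(included):
        site = site_by_id[sid]
        seed_seq = _site_seed(config.seed, sid)
        model = age_depth.fit_age_model(
            controls[sid],
            n_draws=config.n_age_draws,
            seed=seed_seq,
            window_start_ce=config.qc_window_start_ce,
        )
        masked = record_io.apply_depth_mask(site, series[sid])
        try:
            influx = transform.concentration_to_influx(masked, model)
        except ValueError as exc:
            excluded[sid] = f"transform failed: {exc}"
            included.remove(sid)
            continue
        ensembles[sid] = model
        prs[sid] = transform.prs_transform(influx)

    # composites + change points per grouping
    binned = {
        sid: composite.bin_series(
            p,
            bin_width=config.bin_width,
            origin=config.window_start_ce,
            end=config.window_end_ce,
        )
        for sid, p in prs.items()
    }
    composites: dict[str, composite.CompositeCurve] = {}
    changepoints: dict[str, changepoint.ChangePointResult] = {}
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xC0)))
    for attr in config.group_by:
        groups: dict[str, list] = {}
        for sid in included:
            label = getattr(site_by_id[sid], attr)
            groups.setdefault(f"{attr}:{label}", []).append(binned[sid])
        for label, members in sorted(groups.items()):
            if len(members) < max(config.min_group_sites, 2):
                logger.info("skipping composite %s: only %d site(s)", label, len(members))
                continue
            curve = composite.bootstrap_composite(
                members,
                B=config.bootstrap_reps,
                percentiles=config.percentiles,
                seed=int(rng.integers(2**31)),
                window=config.smooth_window,
                label=label,
            )
            composites[label] = curve
            try:
                changepoints[label] = changepoint.changepoint_on_composite(
                    curve, penalty=config.penalty
                )
            except ValueError as exc:
                logger.warning("change point on %s skipped: %s", label, exc)

    # all-tropics composite
    if len(binned) >= 2:
        curve = composite.bootstrap_composite(
            list(binned.values()),
            B=config.bootstrap_reps,
            percentiles=config.percentiles,
            seed=int(rng.integers(2**31)),
            window=config.smooth_window,
            label="all:tropics",
        )
        composites["all:tropics"] = curve
        changepoints["all:tropics"] = changepoint.changepoint_on_composite(
            curve, penalty=config.penalty
        )

    # 20th-century change map
    signals: dict[str, change_map.ChangeSignal] = {}
    signal_excluded: dict[str, str] = {}
    prior = (config.window_start_ce, config.recent_window[0])
    for sid in included:
        try:
            sig = change_map.period_change(
                prs[sid], recent=config.recent_window, prior=prior
            )
        except change_map.PeriodCoverageError as exc:
            signal_excluded[sid] = str(exc)
            continue
        signals[sid] = change_map.classify(sig)

    # per-site summaries and group statistics
    stats = _site_statistics(config, site_by_id, included, prs, signals, covariates)

    manifest = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "n_input_sites": len(sites),
        "n_included": len(included),
        "included": included,
        "excluded": excluded,
        "change_map_excluded": signal_excluded,
        "n_change_map_sites": len(signals),
    }
    result = PipelineResult(
        config=config,
        included=included,
        excluded=excluded,
        ensembles=ensembles,
        prs=prs,
        composites=composites,
        changepoints=changepoints,
        signals=signals,
        signal_excluded=signal_excluded,
        stats=stats,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_outputs(Path(out_dir), result)
    return result


def _site_statistics(
    config: PipelineConfig,
    site_by_id: dict,
    included: list[str],
    prs: dict[str, transform.PRSSeries],
    signals: dict[str, change_map.ChangeSignal],
    covariates: pd.DataFrame | None,
) -> dict:
    rows = []
    for sid in included:
        site = site_by_id[sid]
        med = transform.median_prs(
            prs[sid], window=(config.window_start_ce, config.window_end_ce)
        )
        rows.append(
            {
                "site_id": sid,
                "region": site.region,
                "ecosystem": site.ecosystem,
                "elevation_group": site_stats.assign_elevation_group(site.elevation_m),
                "footprint_class": site_stats.assign_footprint_class(site.footprint),
                "median_prs_cuberoot": transform.cube_root(med) if np.isfinite(med) else np.nan,
            }
        )
    summaries = pd.DataFrame(rows)
    out: dict = {"group_tests": {}, "regression": {}, "pca": None}
    if summaries.empty:
        return out

    for attr in ("region", "ecosystem", "elevation_group", "footprint_class"):
        groups = {
            str(lab): grp["median_prs_cuberoot"].dropna().to_numpy()
            for lab, grp in summaries.groupby(attr)
        }
        groups = {k: v for k, v in groups.items() if len(v) > 0}
        if len(groups) < 2 or sum(len(v) for v in groups.values()) <= len(groups):
            continue
        h, p_kw = site_stats.kruskal_wallis(groups)
        f, p_f = site_stats.one_way_anova(groups)
        out["group_tests"][attr] = {
            "kruskal_wallis": {"H": h, "p": p_kw},
            "anova": {"F": f, "p": p_f},
        }

    # Kruskal-Wallis on 20th-century deltas between regions
    delta_groups: dict[str, list[float]] = {}
    for sid, sig in signals.items():
        delta_groups.setdefault(site_by_id[sid].region, []).append(sig.delta)
    delta_groups = {k: np.asarray(v) for k, v in delta_groups.items() if len(v) > 0}
    if len(delta_groups) >= 2:
        h, p = site_stats.kruskal_wallis(delta_groups)
        out["group_tests"]["region_20c_delta"] = {"kruskal_wallis": {"H": h, "p": p}}

    if covariates is not None:
        merged = summaries.merge(covariates, on="site_id", how="inner")
        cand = [c for c in covariates.columns if c != "site_id"]
        ok = merged["median_prs_cuberoot"].notna()
        merged = merged.loc[ok]
        if len(cand) >= 2 and len(merged) > len(cand) + 2:
            try:
                _, loadings, varexp = site_stats.pca_climate(merged, cand)
                out["pca"] = {
                    "loadings": loadings.to_dict(),
                    "variance_explained_pct": varexp.tolist(),
                }
            except ValueError as exc:
                logger.warning("PCA skipped: %s", exc)
            report = site_stats.screen_and_regress(
                merged,
                response="median_prs_cuberoot",
                candidates=cand,
                r_threshold=config.r_threshold,
                collinearity_threshold=config.collinearity_threshold,
            )
            out["regression"]["0-2000"] = report.to_dict()
    out["summaries"] = summaries.to_dict(orient="records")
    return out


def _write_outputs(out: Path, result: PipelineResult) -> None:
    out.mkdir(parents=True, exist_ok=True)

    chron_rows = []
    for sid, model in sorted(result.ensembles.items()):
        q05 = model.quantile_ages(0.05)
        q95 = model.quantile_ages(0.95)
        for d, med, lo, hi in zip(model.control_depths, model.median_ages, q05, q95):
            chron_rows.append(
                {"site_id": sid, "depth_cm": d, "age_ce_median": med,
                 "age_ce_q05": min(lo, hi), "age_ce_q95": max(lo, hi)}
            )
    pd.DataFrame(chron_rows).to_csv(out / "chronologies.csv", index=False)

    series_rows = []
    for sid, p in sorted(result.prs.items()):
        for age, val in zip(p.age_ce, p.prs):
            series_rows.append({"site_id": sid, "age_ce": age, "prs": val})
    pd.DataFrame(series_rows).to_csv(out / "transformed_series.csv", index=False)

    comp_rows = []
    for label, curve in sorted(result.composites.items()):
        for t, m, lo, hi, ns in zip(
            curve.target_ce, curve.mean, curve.lower, curve.upper, curve.n_sites
        ):
            comp_rows.append(
                {"group": label, "target_ce": t, "mean": m, "q05": lo, "q95": hi,
                 "n_sites": ns}
            )
    pd.DataFrame(comp_rows).to_csv(out / "composites.csv", index=False)

    cp_rows = [
        {
            "group": label,
            "tau_year": r.tau_year,
            "statistic": r.statistic,
            "penalty": r.penalty,
            "significant": r.significant,
            "mean_before": r.mean_before,
            "mean_after": r.mean_after,
        }
        for label, r in sorted(result.changepoints.items())
    ]
    pd.DataFrame(cp_rows).to_csv(out / "changepoints.csv", index=False)

    cm_rows = [
        {
            "site_id": sid,
            "mean_prior": s.mean_prior,
            "mean_recent": s.mean_recent,
            "delta": s.delta,
            "relative": s.relative,
            "signal_class": s.signal_class,
        }
        for sid, s in sorted(result.signals.items())
    ]
    pd.DataFrame(cm_rows).to_csv(out / "change_map.csv", index=False)

    with open(out / "stats_report.json", "w") as fh:
        json.dump(result.stats, fh, indent=2, default=_json_default)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
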