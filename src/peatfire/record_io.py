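"""Read, validate and write the site / charcoal / age-control tables.

The on-disk interchange format is three UTF-8 comma-delimited tables with one
header row:

``sites.csv``
    site_id, region, ecosystem, lat, lon, elevation_m, footprint,
    om_pct, c_pct, is_peat [, mask_top_cm, mask_bottom_cm]
``charcoal.csv``
    site_id, depth_top_cm, depth_bottom_cm, value, unit
``age_controls.csv``
    site_id, depth_cm, age_ce, sd_yr

Depths are cm below surface, increasing downward; sample values belong to the
interval midpoint. Ages are calendar years CE. The optional depth-mask columns
exclude one continuous minerogenic interval per site from the charcoal series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "REGIONS",
    "ECOSYSTEMS",
    "SiteRecord",
    "CharcoalSeries",
    "AgeControlSet",
    "RecordValidationError",
    "read_tables",
    "write_tables",
    "passes_peat_criterion",
    "in_tropics",
    "apply_depth_mask",
]

#: Biogeographic realm labels used as site strata.
REGIONS = ("Neotropical", "Afrotropical", "Indomalayan", "Australasian", "Oceanian")

#: Peatland ecosystem (modern vegetation) labels.
ECOSYSTEMS = ("cushion_sedge", "hardwood_swamp", "palm_swamp", "other")

CONCENTRATION = "concentration"  # particles cm^-3
INFLUX = "influx"                # particles cm^-2 yr^-1


class RecordValidationError(ValueError):
    """Raised when an input table violates the schema or referential rules."""


@dataclass(frozen=True)
class SiteRecord:
    """One peatland (or landscape) charcoal site."""

    site_id: str
    region: str
    ecosystem: str = "other"
    lat: float = 0.0
    lon: float = 0.0
    elevation_m: float = 0.0
    footprint: float = 0.0
    om_pct: float | None = None
    c_pct: float | None = None
    is_peat: bool = True
    mask_top_cm: float | None = None
    mask_bottom_cm: float | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise RecordValidationError(f"{self.site_id}: lat {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise RecordValidationError(f"{self.site_id}: lon {self.lon} outside [-180, 180]")
        if self.region not in REGIONS and self.region != "unknown":
            raise RecordValidationError(
                f"{self.site_id}: region {self.region!r} not one of {REGIONS} or 'unknown'"
            )


@dataclass
class CharcoalSeries:
    """Depth-ordered charcoal measurements for one site (single unit flag)."""

    site_id: str
    depth_top_cm: np.ndarray
    depth_bottom_cm: np.ndarray
    value: np.ndarray
    unit: str = CONCENTRATION

    def __post_init__(self) -> None:
        self.depth_top_cm = np.asarray(self.depth_top_cm, dtype=float)
        self.depth_bottom_cm = np.asarray(self.depth_bottom_cm, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.unit not in (CONCENTRATION, INFLUX):
            raise RecordValidationError(f"{self.site_id}: unknown unit flag {self.unit!r}")
        if np.any(self.value < 0):
            raise RecordValidationError(f"{self.site_id}: negative charcoal value")
        if np.any(self.depth_bottom_cm <= self.depth_top_cm):
            raise RecordValidationError(f"{self.site_id}: non-positive sample thickness")
        if np.any(np.diff(self.depth_top_cm) <= 0):
            raise RecordValidationError(f"{self.site_id}: sample depths must strictly increase")

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.depth_top_cm + self.depth_bottom_cm)

    def __len__(self) -> int:
        return len(self.value)


@dataclass
class AgeControlSet:
    """Calendar-age control points (core top, calibrated 14C, 210Pb/137Cs)."""

    site_id: str
    depth_cm: np.ndarray
    age_ce: np.ndarray
    sd_yr: np.ndarray

    def __post_init__(self) -> None:
        self.depth_cm = np.asarray(self.depth_cm, dtype=float)
        self.age_ce = np.asarray(self.age_ce, dtype=float)
        self.sd_yr = np.asarray(self.sd_yr, dtype=float)
        if np.any(np.diff(self.depth_cm) <= 0):
            raise RecordValidationError(f"{self.site_id}: control depths must strictly increase")
        if np.any(self.sd_yr <= 0):
            raise RecordValidationError(f"{self.site_id}: control sd_yr must be > 0")

    def __len__(self) -> int:
        return len(self.depth_cm)


def _opt(v) -> float | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def read_tables(
    sites_path, charcoal_path, controls_path
) -> tuple[list[SiteRecord], dict[str, CharcoalSeries], dict[str, AgeControlSet]]:
    """Read and cross-validate the three tables.

    Every charcoal series and control set must join to a site; a dangling
    ``site_id`` or a negative value is a hard error that names the offender
    and, where row-local, the line number.
    """
    sites_df = pd.read_csv(sites_path, dtype={"site_id": str})
    charcoal_df = pd.read_csv(charcoal_path, dtype={"site_id": str})
    controls_df = pd.read_csv(controls_path, dtype={"site_id": str})

    required = {
        "sites": ({"site_id", "region", "ecosystem", "lat", "lon", "elevation_m", "footprint"},
                  sites_df),
        "charcoal": ({"site_id", "depth_top_cm", "depth_bottom_cm", "value", "unit"}, charcoal_df),
        "age_controls": ({"site_id", "depth_cm", "age_ce", "sd_yr"}, controls_df),
    }
    for name, (cols, df) in required.items():
        missing = cols - set(df.columns)
        if missing:
            raise RecordValidationError(f"{name} table missing columns: {sorted(missing)}")

    if sites_df["site_id"].duplicated().any():
        dups = sites_df.loc[sites_df["site_id"].duplicated(), "site_id"].tolist()
        raise RecordValidationError(f"duplicate site_id in sites table: {dups}")

    sites: list[SiteRecord] = []
    for _, row in sites_df.iterrows():
        sites.append(
            SiteRecord(
                site_id=row["site_id"],
                region=row["region"],
                ecosystem=row.get("ecosystem", "other"),
                lat=float(row["lat"]),
                lon=float(row["lon"]),
                elevation_m=float(row["elevation_m"]),
                footprint=float(row["footprint"]),
                om_pct=_opt(row.get("om_pct")),
                c_pct=_opt(row.get("c_pct")),
                is_peat=bool(row.get("is_peat", True)),
                mask_top_cm=_opt(row.get("mask_top_cm")),
                mask_bottom_cm=_opt(row.get("mask_bottom_cm")),
            )
        )
    known = {s.site_id for s in sites}

    for name, df in (("charcoal", charcoal_df), ("age_controls", controls_df)):
        bad = df.loc[~df["site_id"].isin(known)]
        if len(bad):
            # +2: header row and 1-based counting
            lines = (bad.index + 2).tolist()
            ids = sorted(bad["site_id"].unique())
            raise RecordValidationError(
                f"{name} table references unknown site_id {ids} (lines {lines})"
            )
        numeric = df.drop(columns=["site_id", "unit"], errors="ignore")
        nan_rows = numeric.isna().any(axis=1)
        if nan_rows.any():
            lines = (numeric.index[nan_rows] + 2).tolist()
            raise RecordValidationError(f"{name} table has malformed rows at lines {lines}")

    series: dict[str, CharcoalSeries] = {}
    for sid, grp in charcoal_df.groupby("site_id", sort=False):
        units = grp["unit"].unique()
        if len(units) != 1:
            raise RecordValidationError(f"{sid}: mixed unit flags {units.tolist()}")
        grp = grp.sort_values("depth_top_cm")
        series[sid] = CharcoalSeries(
            site_id=sid,
            depth_top_cm=grp["depth_top_cm"].to_numpy(),
            depth_bottom_cm=grp["depth_bottom_cm"].to_numpy(),
            value=grp["value"].to_numpy(),
            unit=units[0],
        )

    controls: dict[str, AgeControlSet] = {}
    for sid, grp in controls_df.groupby("site_id", sort=False):
        grp = grp.sort_values("depth_cm")
        controls[sid] = AgeControlSet(
            site_id=sid,
            depth_cm=grp["depth_cm"].to_numpy(),
            age_ce=grp["age_ce"].to_numpy(),
            sd_yr=grp["sd_yr"].to_numpy(),
        )

    return sites, series, controls


def write_tables(
    out_dir,
    sites: list[SiteRecord],
    series: dict[str, CharcoalSeries],
    controls: dict[str, AgeControlSet],
) -> dict[str, str]:
    """Write the three tables under *out_dir*; returns the paths written."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sites_df = pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "region": [s.region for s in sites],
            "ecosystem": [s.ecosystem for s in sites],
            "lat": [s.lat for s in sites],
            "lon": [s.lon for s in sites],
            "elevation_m": [s.elevation_m for s in sites],
            "footprint": [s.footprint for s in sites],
            "om_pct": [s.om_pct for s in sites],
            "c_pct": [s.c_pct for s in sites],
            "is_peat": [s.is_peat for s in sites],
            "mask_top_cm": [s.mask_top_cm for s in sites],
            "mask_bottom_cm": [s.mask_bottom_cm for s in sites],
        }
    )
    charcoal_df = pd.concat(
        [
            pd.DataFrame(
                {
                    "site_id": cs.site_id,
                    "depth_top_cm": cs.depth_top_cm,
                    "depth_bottom_cm": cs.depth_bottom_cm,
                    "value": cs.value,
                    "unit": cs.unit,
                }
            )
            for cs in series.values()
        ],
        ignore_index=True,
    )
    controls_df = pd.concat(
        [
            pd.DataFrame(
                {
                    "site_id": ac.site_id,
                    "depth_cm": ac.depth_cm,
                    "age_ce": ac.age_ce,
                    "sd_yr": ac.sd_yr,
                }
            )
            for ac in controls.values()
        ],
        ignore_index=True,
    )
    paths = {
        "sites": str(out / "sites.csv"),
        "charcoal": str(out / "charcoal.csv"),
        "age_controls": str(out / "age_controls.csv"),
    }
    sites_df.to_csv(paths["sites"], index=False)
    charcoal_df.to_csv(paths["charcoal"], index=False)
    controls_df.to_csv(paths["age_controls"], index=False)
    return paths


def passes_peat_criterion(site: SiteRecord) -> tuple[bool, str]:
    """Apply the peat-layer criterion: >=30% organic matter, or >=15% carbon,
    or — when neither measurement is available — the publication description
    (``is_peat`` flag).

    Returns (flag, reason) where the reason names the rule that fired.
    """
    if site.om_pct is not None and site.om_pct >= 30.0:
        return True, f"organic matter {site.om_pct:g}% >= 30%"
    if site.c_pct is not None and site.c_pct >= 15.0:
        return True, f"carbon {site.c_pct:g}% >= 15%"
    if site.om_pct is None and site.c_pct is None:
        if site.is_peat:
            return True, "publication description (is_peat flag)"
        return False, "no measurements and publication does not describe peat"
    return False, (
        f"organic matter {site.om_pct}% < 30% and carbon {site.c_pct}% < 15%"
    )


def in_tropics(site: SiteRecord, allowlist: frozenset[str] | set[str] = frozenset()) -> bool:
    """True iff |lat| <= 30 (closed interval) or the site is explicitly
    allowlisted (near-boundary sites retained by expert judgement)."""
    return abs(site.lat) <= 30.0 or site.site_id in allowlist


def apply_depth_mask(site: SiteRecord, series: CharcoalSeries) -> CharcoalSeries:
    """Drop samples whose midpoint falls in the site's masked (minerogenic)
    depth interval. No-op when the site carries no mask."""
    if site.mask_top_cm is None or site.mask_bottom_cm is None:
        return series
    mid = series.midpoints
    keep = ~((mid >= site.mask_top_cm) & (mid <= site.mask_bottom_cm))
    return replace(
        series,
        depth_top_cm=series.depth_top_cm[keep],
        depth_bottom_cm=series.depth_bottom_cm[keep],
        value=series.value[keep],
    )
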