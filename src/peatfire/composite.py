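"""Regional composite burning curves.

A composite is built in two stages: (a) each site's PRS series is averaged
into non-overlapping 25-yr bins over 0–2000 CE, and (b) the cross-site mean
per bin is smoothed with a 200-yr-window locally weighted (tricube, locally
linear) smoother. Uncertainty comes from bootstrap resampling of sites: the
per-bin means are recomputed and smoothed for each of B resamples and the
5%/95% percentiles per target form the confidence band.

The smoother uses a fixed *metric* half-window (window/2 years on either side
of the target), so on a fixed grid without gaps it is a linear operator; the
bootstrap exploits that by precomputing the smoother matrix once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .record_io import SiteRecord
from .transform import PRSSeries

__all__ = [
    "BinnedSeries",
    "CompositeCurve",
    "bin_series",
    "lowess_smooth",
    "smoother_matrix",
    "bootstrap_composite",
    "haversine_km",
    "select_landscape_sites",
]

EARTH_RADIUS_KM = 6371.0

DEFAULT_BIN_WIDTH = 25.0
DEFAULT_ORIGIN_CE = 0.0
DEFAULT_END_CE = 2000.0
DEFAULT_SMOOTH_WINDOW = 200.0
DEFAULT_BOOTSTRAP_REPS = 1000
DEFAULT_PERCENTILES = (5.0, 95.0)


@dataclass
class BinnedSeries:
    """One site's PRS series averaged into fixed-width, non-overlapping bins.

    Bin k covers [origin + k·w, origin + (k+1)·w); empty bins carry NaN
    (absence of samples, not absence of burning).
    """

    site_id: str
    bin_start: np.ndarray
    bin_width: float
    mean_prs: np.ndarray
    n_samples: np.ndarray

    @property
    def bin_mid(self) -> np.ndarray:
        return self.bin_start + 0.5 * self.bin_width


@dataclass
class CompositeCurve:
    """Smoothed multi-site mean burning curve with a bootstrap band."""

    group: str
    target_ce: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_sites: np.ndarray
    n_group: int
    percentiles: tuple[float, float]
    n_boot: int
    seed: int


def bin_series(
    series: PRSSeries,
    bin_width: float = DEFAULT_BIN_WIDTH,
    origin: float = DEFAULT_ORIGIN_CE,
    end: float = DEFAULT_END_CE,
) -> BinnedSeries:
    """Average a PRS series into fixed bins over [origin, end).

    Samples outside [origin, end) are excluded. Bin value = arithmetic mean
    of the member PRS values; empty bins are NaN.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    n_bins = int(np.ceil((end - origin) / bin_width))
    starts = origin + bin_width * np.arange(n_bins)

    sel = (series.age_ce >= origin) & (series.age_ce < end)
    ages = series.age_ce[sel]
    vals = series.prs[sel]
    idx = np.floor((ages - origin) / bin_width).astype(int)

    sums = np.bincount(idx, weights=vals, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    return BinnedSeries(
        site_id=series.site_id,
        bin_start=starts,
        bin_width=float(bin_width),
        mean_prs=means,
        n_samples=counts,
    )


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def smoother_matrix(x: np.ndarray, targets: np.ndarray, window: float) -> np.ndarray:
    """Linear-operator form of the locally weighted smoother.

    Row t gives weights l such that smoothed[t] = l @ y, for tricube-weighted
    local linear regression with metric half-window window/2 around each
    target. Targets with fewer than 2 in-window points fall back to the
    tricube-weighted mean (or nearest point if none are in window).
    """
    x = np.asarray(x, dtype=float)
    targets = np.asarray(targets, dtype=float)
    h = window / 2.0
    S = np.zeros((len(targets), len(x)))
    for t, x0 in enumerate(targets):
        d = x - x0
        w = _tricube(d / h)
        nz = np.count_nonzero(w)
        if nz >= 2:
            s0 = w.sum()
            s1 = (w * d).sum()
            s2 = (w * d * d).sum()
            denom = s0 * s2 - s1 * s1
            if denom > 1e-12 * max(s0 * s2, 1e-300):
                S[t] = w * (s2 - d * s1) / denom
                continue
        if nz >= 1:  # weighted-mean fallback
            S[t] = w / w.sum()
        else:  # no in-window point: nearest neighbour keeps output finite
            S[t, np.argmin(np.abs(d))] = 1.0
    return S


def lowess_smooth(
    x: np.ndarray,
    y: np.ndarray,
    window: float = DEFAULT_SMOOTH_WINDOW,
    targets: np.ndarray | None = None,
) -> np.ndarray:
    """Tricube-weighted local linear smoothing with a fixed metric window.

    NaN values in *y* are ignored; if all values are NaN the output is all
    NaN. Deterministic; exactly reproduces constants and straight lines where
    at least two points fall in the window.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if window <= 0:
        raise ValueError("window must be > 0")
    if targets is None:
        targets = x
    targets = np.asarray(targets, dtype=float)
    finite = np.isfinite(y)
    if finite.sum() == 0:
        return np.full(len(targets), np.nan)
    if finite.sum() < 2:
        return np.full(len(targets), float(y[finite][0]))
    S = smoother_matrix(x[finite], targets, window)
    return S @ y[finite]


def _stack_group(group: list[BinnedSeries]) -> tuple[np.ndarray, np.ndarray, float]:
    g0 = group[0]
    for g in group[1:]:
        if (
            g.bin_width != g0.bin_width
            or len(g.bin_start) != len(g0.bin_start)
            or g.bin_start[0] != g0.bin_start[0]
        ):
            raise ValueError("all binned series in a group must share the bin grid")
    M = np.vstack([g.mean_prs for g in group])
    return M, g0.bin_mid, g0.bin_width


def bootstrap_composite(
    group: list[BinnedSeries],
    B: int = DEFAULT_BOOTSTRAP_REPS,
    percentiles: tuple[float, float] = DEFAULT_PERCENTILES,
    seed: int = 0,
    window: float = DEFAULT_SMOOTH_WINDOW,
    label: str = "",
) -> CompositeCurve:
    """Composite curve for a group of binned site series.

    Point curve: per-bin NaN-ignoring mean across sites, then smoothed.
    Band: sites resampled with replacement B times; each resample's per-bin
    means are smoothed identically and the per-target percentiles form the
    band. Bins with no contributing site are skipped as smoothing targets.
    Sites are ordered by site_id before resampling so the result is invariant
    to the input order.
    """
    if len(group) < 2:
        raise ValueError("composite needs >= 2 sites (band undefined for 1)")
    if B < 1:
        raise ValueError("B must be >= 1")
    group = sorted(group, key=lambda g: g.site_id)
    M, mids, _ = _stack_group(group)
    n_sites_bin = np.sum(np.isfinite(M), axis=0)
    support = n_sites_bin > 0
    if support.sum() < 2:
        raise ValueError("fewer than 2 populated bins; composite undefined")
    x = mids[support]
    Msup = M[:, support]

    with np.errstate(invalid="ignore"):
        point_raw = np.nanmean(Msup, axis=0)
    S = smoother_matrix(x, x, window)
    point = S @ point_raw

    rng = np.random.default_rng(seed)
    n = len(group)
    idx = rng.integers(0, n, size=(B, n))
    boot = np.empty((B, support.sum()))
    resampled = Msup[idx]  # (B, n, n_bins)
    with warnings.catch_warnings():
        # a resample may miss every site covering a bin; NaN there is intended
        warnings.simplefilter("ignore", RuntimeWarning)
        raw = np.nanmean(resampled, axis=1)
    full = np.all(np.isfinite(raw), axis=1)
    if np.any(full):
        boot[full] = raw[full] @ S.T
    for b in np.flatnonzero(~full):
        boot[b] = lowess_smooth(x, raw[b], window=window, targets=x)
    lo, hi = percentiles
    lower = np.nanpercentile(boot, lo, axis=0)
    upper = np.nanpercentile(boot, hi, axis=0)

    return CompositeCurve(
        group=label,
        target_ce=x,
        mean=point,
        lower=lower,
        upper=upper,
        n_sites=n_sites_bin[support],
        n_group=n,
        percentiles=(float(lo), float(hi)),
        n_boot=B,
        seed=seed,
    )


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km (haversine, R = 6371 km)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(v, dtype=float)) for v in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def select_landscape_sites(
    peat_sites: list[SiteRecord],
    candidates: list[SiteRecord],
    radius_km: float = 800.0,
) -> list[SiteRecord]:
    """Retain candidate (landscape) sites within *radius_km* great-circle
    distance of at least one peat site."""
    if not peat_sites:
        return []
    plat = np.array([s.lat for s in peat_sites])
    plon = np.array([s.lon for s in peat_sites])
    kept = []
    for c in candidates:
        d = haversine_km(c.lat, c.lon, plat, plon)
        if np.min(d) <= radius_km:
            kept.append(c)
    return kept
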