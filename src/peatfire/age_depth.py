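"""Monte-Carlo piecewise-linear age-depth models.

Chronologies are built from already-calibrated calendar-age control points by
repeatedly perturbing every control age with its Gaussian uncertainty and
keeping only draws that remain stratigraphically ordered (age strictly
decreasing in CE — i.e. strictly older — with depth). Depths between controls
are linearly interpolated; no extrapolation beyond the outermost controls.

This is a deliberately light-weight chronology: downstream the pipeline needs
only dated samples and per-segment accumulation rates, so the full Bayesian
autoregressive machinery used for real cores is not reproduced here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .record_io import AgeControlSet

__all__ = [
    "AgeModelEnsemble",
    "ChronologyQCError",
    "passes_chronology_qc",
    "fit_age_model",
    "accumulation_rate",
]

#: Default QC window start: 3000 years before 2000 CE.
QC_WINDOW_START_CE = -1000.0
#: Minimum age controls inside the QC window.
QC_MIN_CONTROLS = 2

_MAX_REJECTION_ATTEMPTS = 1000


class ChronologyQCError(ValueError):
    """Raised when a control set fails the chronology quality-control rule."""


@dataclass
class AgeModelEnsemble:
    """Ensemble of monotone depth→age chronologies for one site.

    ``draws`` has shape (n_draws, n_controls): sampled ages (CE) at the
    control depths. ``flagged`` marks draws where rejection sampling failed
    and the ages were sorted into order instead.
    """

    site_id: str
    control_depths: np.ndarray
    draws: np.ndarray
    median_ages: np.ndarray
    n_draws: int
    seed: int
    flagged: np.ndarray

    @property
    def depth_range(self) -> tuple[float, float]:
        return float(self.control_depths[0]), float(self.control_depths[-1])

    def _check_range(self, depth: np.ndarray) -> None:
        lo, hi = self.depth_range
        if np.any(depth < lo) or np.any(depth > hi):
            raise ValueError(
                f"{self.site_id}: depth outside modelled range [{lo}, {hi}] "
                "(no extrapolation beyond the outermost age controls)"
            )

    def age_at(self, depth) -> np.ndarray:
        """Median-chronology age (CE) at *depth* by linear interpolation."""
        depth = np.atleast_1d(np.asarray(depth, dtype=float))
        self._check_range(depth)
        return np.interp(depth, self.control_depths, self.median_ages)

    def in_range(self, depth) -> np.ndarray:
        depth = np.atleast_1d(np.asarray(depth, dtype=float))
        lo, hi = self.depth_range
        return (depth >= lo) & (depth <= hi)

    def quantile_ages(self, q: float) -> np.ndarray:
        """Per-control-depth quantile of the ensemble ages."""
        return np.quantile(self.draws, q, axis=0)


def passes_chronology_qc(
    controls: AgeControlSet, window_start_ce: float = QC_WINDOW_START_CE
) -> bool:
    """True iff at least two age controls fall within the last 3000 years
    (ages >= *window_start_ce*), the inclusion rule for composite records."""
    return int(np.sum(controls.age_ce >= window_start_ce)) >= QC_MIN_CONTROLS


def fit_age_model(
    controls: AgeControlSet,
    n_draws: int = 1000,
    seed: int = 0,
    window_start_ce: float = QC_WINDOW_START_CE,
) -> AgeModelEnsemble:
    """Build a Monte-Carlo chronology ensemble from calendar-age controls.

    Each draw samples every control age from Normal(age_ce, sd_yr) and is
    accepted only if ages strictly decrease (CE) with depth; a draw is
    re-sampled up to 1000 times, after which it is sorted into order and
    flagged. Controls must first pass the chronology QC rule.
    """
    if not passes_chronology_qc(controls, window_start_ce):
        raise ChronologyQCError(
            f"{controls.site_id}: fewer than {QC_MIN_CONTROLS} age controls "
            f"younger than {window_start_ce:g} CE"
        )
    if len(controls) < 2:
        raise ChronologyQCError(f"{controls.site_id}: need >= 2 age controls")

    rng = np.random.default_rng(seed)
    n_ctrl = len(controls)
    draws = np.empty((n_draws, n_ctrl))
    flagged = np.zeros(n_draws, dtype=bool)

    pending = np.arange(n_draws)
    for _ in range(_MAX_REJECTION_ATTEMPTS):
        if pending.size == 0:
            break
        cand = rng.normal(controls.age_ce, controls.sd_yr, size=(pending.size, n_ctrl))
        ok = np.all(np.diff(cand, axis=1) < 0, axis=1)
        draws[pending[ok]] = cand[ok]
        # keep the latest candidate for still-pending draws so the sorted
        # fallback acts on a genuine sample
        draws[pending[~ok]] = cand[~ok]
        pending = pending[~ok]
    if pending.size:
        srt = -np.sort(-draws[pending], axis=1)  # descending CE with depth
        # break exact ties so accumulation rates stay finite
        srt -= np.arange(n_ctrl) * 1e-6
        draws[pending] = srt
        flagged[pending] = True

    median_ages = np.median(draws, axis=0)
    # medians of monotone draws are monotone, but guard against numerics
    if np.any(np.diff(median_ages) >= 0):
        raise RuntimeError(f"{controls.site_id}: median chronology not monotone")

    return AgeModelEnsemble(
        site_id=controls.site_id,
        control_depths=controls.depth_cm.copy(),
        draws=draws,
        median_ages=median_ages,
        n_draws=n_draws,
        seed=seed,
        flagged=flagged,
    )


def accumulation_rate(model: AgeModelEnsemble, depth) -> np.ndarray:
    """Median (across draws) peat accumulation rate, cm/yr, at *depth*.

    Within each draw the rate is the segment quotient Δdepth/Δage for the
    piecewise-linear segment containing the depth; a depth exactly at an
    interior control belongs to the segment above it.
    """
    depth = np.atleast_1d(np.asarray(depth, dtype=float))
    model._check_range(depth)
    d = model.control_depths
    seg = np.clip(np.searchsorted(d, depth, side="left") - 1, 0, len(d) - 2)
    ddepth = d[seg + 1] - d[seg]
    # ages decrease in CE with depth, so elapsed years = age[seg] - age[seg+1]
    dage = model.draws[:, seg] - model.draws[:, seg + 1]  # (n_draws, n_depth)
    rates = ddepth / dage
    return np.median(rates, axis=0)
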