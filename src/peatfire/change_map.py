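"""Per-site 20th-century change in burning and its eight-class signal label.

For each site the mean PRS over 1900–2000 CE is contrasted with the mean over
0–1900 CE; the difference (delta) and the relative change (delta divided by
the 0–2000 CE mean) summarise whether burning rose or fell in the 20th
century. Deltas are mapped onto ordered signal classes, from "extremely
strong positive" (> 50) through "no change" (exactly 0) to "strong negative"
(−50 to −15); deltas below −50 receive a mirrored "extremely strong negative"
class (flagged — an extension beyond the published table, which stops at −50).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .transform import PRSSeries

__all__ = [
    "SIGNAL_CLASSES",
    "ChangeSignal",
    "PeriodCoverageError",
    "period_change",
    "classify_change",
    "classify",
]

RECENT_WINDOW = (1900.0, 2000.0)  # inclusive both ends
PRIOR_WINDOW = (0.0, 1900.0)      # 1900 CE belongs to the recent window only

EXTREMELY_STRONG_POSITIVE = "extremely strong positive"
STRONG_POSITIVE = "strong positive"
POSITIVE = "positive"
WEAK_POSITIVE = "weak positive"
NO_CHANGE = "no change"
WEAK_NEGATIVE = "weak negative"
NEGATIVE = "negative"
STRONG_NEGATIVE = "strong negative"
EXTREMELY_STRONG_NEGATIVE = "extremely strong negative"

#: Ordered from most negative to most positive.
SIGNAL_CLASSES = (
    EXTREMELY_STRONG_NEGATIVE,
    STRONG_NEGATIVE,
    NEGATIVE,
    WEAK_NEGATIVE,
    NO_CHANGE,
    WEAK_POSITIVE,
    POSITIVE,
    STRONG_POSITIVE,
    EXTREMELY_STRONG_POSITIVE,
)

POSITIVE_CLASSES = frozenset(
    {WEAK_POSITIVE, POSITIVE, STRONG_POSITIVE, EXTREMELY_STRONG_POSITIVE}
)

# Boundary convention: intervals are closed on the side away from zero,
# mirrored for negatives, so e.g. delta = 15 is "positive" and delta = -15 is
# "negative". A single table so an alternate convention is a one-line change.
_CLASS_TABLE = (
    # (lower, upper, lower_closed, upper_closed, label)
    (50.0, math.inf, False, False, EXTREMELY_STRONG_POSITIVE),
    (15.0, 50.0, False, True, STRONG_POSITIVE),
    (5.0, 15.0, False, True, POSITIVE),
    (0.0, 5.0, False, True, WEAK_POSITIVE),
    (0.0, 0.0, True, True, NO_CHANGE),
    (-5.0, 0.0, True, False, WEAK_NEGATIVE),
    (-15.0, -5.0, True, False, NEGATIVE),
    (-50.0, -15.0, True, False, STRONG_NEGATIVE),
    (-math.inf, -50.0, False, False, EXTREMELY_STRONG_NEGATIVE),
)


class PeriodCoverageError(ValueError):
    """Raised when a site lacks samples in one of the contrast windows."""


@dataclass
class ChangeSignal:
    """Period-contrast summary for one site."""

    site_id: str
    mean_recent: float
    mean_prior: float
    delta: float
    relative: float  # NaN when the whole-period mean is 0
    signal_class: str | None = None
    flagged: bool = False  # True for the out-of-table extremely-strong-negative class


def period_change(
    series: PRSSeries,
    recent: tuple[float, float] = RECENT_WINDOW,
    prior: tuple[float, float] = PRIOR_WINDOW,
) -> ChangeSignal:
    """Contrast mean PRS in the recent window against the prior window.

    Window means are arithmetic means of the raw sample PRS values with ages
    in-window (recent inclusive both ends, prior half-open at its upper end).
    A site without samples in both windows raises PeriodCoverageError and is
    excluded upstream with a logged reason.
    """
    age = series.age_ce
    in_recent = (age >= recent[0]) & (age <= recent[1])
    in_prior = (age >= prior[0]) & (age < prior[1])
    if not np.any(in_recent):
        raise PeriodCoverageError(
            f"{series.site_id}: no samples in recent window {recent}"
        )
    if not np.any(in_prior):
        raise PeriodCoverageError(
            f"{series.site_id}: no samples in prior window {prior}"
        )
    mean_recent = float(np.mean(series.prs[in_recent]))
    mean_prior = float(np.mean(series.prs[in_prior]))
    delta = mean_recent - mean_prior

    whole = (age >= prior[0]) & (age <= recent[1])
    whole_mean = float(np.mean(series.prs[whole]))
    relative = delta / whole_mean if whole_mean > 0 else float("nan")

    return ChangeSignal(
        site_id=series.site_id,
        mean_recent=mean_recent,
        mean_prior=mean_prior,
        delta=delta,
        relative=relative,
    )


def classify_change(delta: float) -> str:
    """Map a period-contrast delta onto its signal class."""
    if not math.isfinite(delta):
        raise ValueError("delta must be finite; unclassifiable")
    for lo, hi, lo_closed, hi_closed, label in _CLASS_TABLE:
        above = delta > lo or (lo_closed and delta == lo)
        below = delta < hi or (hi_closed and delta == hi)
        if above and below:
            return label
    raise AssertionError("class table does not cover the real line")


def classify(signal: ChangeSignal) -> ChangeSignal:
    """Attach the signal class (and extension flag) to a ChangeSignal."""
    signal.signal_class = classify_change(signal.delta)
    signal.flagged = signal.signal_class == EXTREMELY_STRONG_NEGATIVE
    return signal
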