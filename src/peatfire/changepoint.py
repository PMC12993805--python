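"""At-most-one-change (AMOC) detection of a joint mean/variance change.

Under a Gaussian likelihood the cost of a segment is n·log(σ̂²_MLE). The AMOC
statistic is twice the log-likelihood gain of the best two-segment split over
the unsplit series::

    statistic = cost(y) − min_τ [ cost(y[:τ]) + cost(y[τ:]) ]

with τ the length of the first segment, constrained so both segments hold at
least two points. The change is significant when the statistic exceeds the
penalty; the default penalty is an MBIC-style 4·log(n) (three extra segment
parameters plus the change-location term). Degenerate (zero-variance)
segments are handled with a variance floor so the log stays finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .composite import CompositeCurve

__all__ = [
    "VARIANCE_FLOOR",
    "ChangePointResult",
    "segment_cost",
    "mbic_penalty",
    "amoc_meanvar",
    "changepoint_on_composite",
]

VARIANCE_FLOOR = 1e-12
MIN_SEGMENT = 2


@dataclass
class ChangePointResult:
    """Best single change point of a series under the mean/variance model.

    ``tau_index`` is the length of the first segment (the split is between
    ``y[tau_index-1]`` and ``y[tau_index]``); ``tau_year`` is the target year
    at the first point of the *second* segment — the year the new regime
    takes effect — when the series is a dated curve.
    """

    tau_index: int
    tau_year: float | None
    statistic: float
    penalty: float
    significant: bool
    mean_before: float
    mean_after: float
    var_before: float
    var_after: float
    floored: bool = False
    group: str = ""


def segment_cost(y: np.ndarray) -> float:
    """Gaussian segment cost n·log(σ̂²_MLE), variance floored at 1e-12."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < MIN_SEGMENT:
        raise ValueError("segment cost needs at least 2 points")
    var = float(np.mean((y - np.mean(y)) ** 2))
    return n * float(np.log(max(var, VARIANCE_FLOOR)))


def mbic_penalty(n: int) -> float:
    """Default penalty: 4·log(n)."""
    return 4.0 * float(np.log(n))


def amoc_meanvar(y: np.ndarray, penalty: float | str = "MBIC") -> ChangePointResult:
    """Exhaustive at-most-one-change search for a joint mean/variance shift.

    All admissible splits τ ∈ [2, n−2] are evaluated with cumulative sums;
    ties break toward the smallest τ. The statistic is invariant to adding a
    constant to the series.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2 * MIN_SEGMENT:
        raise ValueError(f"AMOC needs at least {2 * MIN_SEGMENT} points")
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite values")
    pen = mbic_penalty(n) if isinstance(penalty, str) else float(penalty)

    # exact two-pass segment costs: a constant segment has variance exactly 0
    # (then floored), which one-pass cumulative sums cannot guarantee
    taus = np.arange(MIN_SEGMENT, n - MIN_SEGMENT + 1)
    split_cost = np.array(
        [segment_cost(y[:tau]) + segment_cost(y[tau:]) for tau in taus]
    )

    best = int(np.argmin(split_cost))  # argmin takes the first minimum: smallest tau
    tau = int(taus[best])
    statistic = segment_cost(y) - float(split_cost[best])
    statistic = max(statistic, 0.0)

    left, right = y[:tau], y[tau:]
    floored = bool(
        np.var(left) <= VARIANCE_FLOOR or np.var(right) <= VARIANCE_FLOOR
    )
    return ChangePointResult(
        tau_index=tau,
        tau_year=None,
        statistic=statistic,
        penalty=pen,
        significant=statistic > pen,
        mean_before=float(np.mean(left)),
        mean_after=float(np.mean(right)),
        var_before=float(np.var(left)),
        var_after=float(np.var(right)),
        floored=floored,
    )


def changepoint_on_composite(
    curve: CompositeCurve, penalty: float | str = "MBIC"
) -> ChangePointResult:
    """Run AMOC on the smoothed mean series of a composite curve."""
    finite = np.isfinite(curve.mean)
    y = curve.mean[finite]
    t = curve.target_ce[finite]
    if len(y) < 2 * MIN_SEGMENT:
        raise ValueError(f"{curve.group}: composite has fewer than 4 finite targets")
    res = amoc_meanvar(y, penalty=penalty)
    res.tau_year = float(t[res.tau_index])
    res.group = curve.group
    return res
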