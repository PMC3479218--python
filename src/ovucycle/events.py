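"""Cycle-event detection and the surge arithmetic.

Given any four-hormone series (the packaged reference cycle, a noisy
replicate, or simulator output spanning several cycles) this module finds
the LH surge, aligns day labels to it, and computes the quantities the
model is anchored on: the fold-increase of the surge over the follicular
plateau, the post-surge retention (the fraction of peak LH remaining one
day later, read as the fraction of pituitary GnRH receptors surviving
downregulation), and the timing of the progesterone peak and the luteal
LH minimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import CoverageError
from .reference_data import HormoneSeries

__all__ = [
    "EventTable",
    "detect_surge_day",
    "detect_surge_days",
    "align_to_surge",
    "event_table",
]

#: Relative-day window that defines the follicular baseline (its median LH).
FOLLICULAR_WINDOW = (-14, -5)

#: Relative-day window searched for the luteal LH minimum.
LUTEAL_WINDOW = (1, 13)


@dataclass(frozen=True)
class EventTable:
    """Event summary of one (aligned) cycle.

    ``retention_pct + reduction_pct == 100`` by construction;
    ``period_days`` is None for single-cycle input; the mode-switch days
    are None unless simulator events were supplied.
    """

    surge_day: int
    follicular_lh: float
    surge_ratio: float
    retention_pct: float
    reduction_pct: float
    pg_peak_day: int
    lh_min_day: int
    period_days: float | None = None
    mode_on_day: int | None = None
    mode_off_day: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def detect_surge_day(series: HormoneSeries) -> int:
    """Day label of the global LH maximum (ties broken toward the earliest)."""
    return int(series.days[int(np.argmax(series.lh))])


def detect_surge_days(series: HormoneSeries, min_separation: int = 14) -> list[int]:
    """Day labels of all LH surge peaks in a possibly multi-cycle series.

    Peaks are prominent local maxima at least ``min_separation`` days
    apart; for a series containing a single cycle this reduces to the
    global maximum.
    """
    lh = series.lh
    span = float(lh.max() - lh.min())
    if span <= 0:
        return [int(series.days[0])]
    idx, _ = find_peaks(lh, distance=min_separation, prominence=0.25 * span)
    if idx.size == 0:
        return [detect_surge_day(series)]
    return [int(series.days[i]) for i in idx]


def align_to_surge(series: HormoneSeries) -> HormoneSeries:
    """Translate day labels so the detected surge day becomes 0."""
    return series.shifted(-detect_surge_day(series))


def _reference_surge(series: HormoneSeries, surges: list[int]) -> int:
    """Last surge whose full -14..+13 window lies inside the series."""
    lo, hi = int(series.days[0]), int(series.days[-1])
    covered = [s for s in surges if s - 14 >= lo and s + 13 <= hi]
    if not covered:
        missing = []
        for s in surges:
            missing.extend(d for d in range(s - 14, s + 14) if d < lo or d > hi)
        raise CoverageError(
            f"no surge with full -14..+13 coverage; days missing around "
            f"detected surges {surges}: {sorted(set(missing))}"
        )
    return covered[-1]


def event_table(
    series: HormoneSeries, events: list[tuple[float, str]] | None = None
) -> EventTable:
    """Compute the event summary of the last fully covered cycle.

    The series may span several cycles; the summary is computed on the
    last surge with a complete -14..+13 window.  ``events`` may carry
    simulator ``mode_on`` / ``mode_off`` events (absolute times in days);
    a switch is assigned to the sampled day containing it.
    """
    surges = detect_surge_days(series)
    period = None
    if len(surges) >= 2:
        period = float(np.mean(np.diff(surges)))
    surge = _reference_surge(series, surges)
    cycle = series.window(surge - 14, surge + 13).shifted(-surge)

    fl_lo, fl_hi = FOLLICULAR_WINDOW
    follicular = np.median(
        cycle.lh[(cycle.days >= fl_lo) & (cycle.days <= fl_hi)]
    )
    lh0 = cycle.value_at("lh", 0)
    lh1 = cycle.value_at("lh", 1)
    retention = 100.0 * lh1 / lh0
    pg_peak = int(cycle.days[int(np.argmax(cycle.progesterone))])
    lut = (cycle.days >= LUTEAL_WINDOW[0]) & (cycle.days <= LUTEAL_WINDOW[1])
    lh_min = int(cycle.days[lut][int(np.argmin(cycle.lh[lut]))])

    mode_on = mode_off = None
    if events:
        on_days = [math.floor(t) - surge for t, n in events if n == "mode_on"]
        off_days = [math.floor(t) - surge for t, n in events if n == "mode_off"]
        # the switch belonging to this cycle: last mode_on at or before the
        # surge, first mode_off after it
        before = [d for d in on_days if -14 <= d <= 0]
        after = [d for d in off_days if 0 < d <= 14]
        mode_on = before[-1] if before else None
        mode_off = after[0] if after else None

    return EventTable(
        surge_day=surge,
        follicular_lh=float(follicular),
        surge_ratio=float(lh0 / follicular),
        retention_pct=float(retention),
        reduction_pct=float(100.0 - retention),
        pg_peak_day=pg_peak,
        lh_min_day=lh_min,
        period_days=period,
        mode_on_day=mode_on,
        mode_off_day=mode_off,
    )
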