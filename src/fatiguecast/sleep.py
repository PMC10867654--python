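"""Sleep/wake estimation from wrist acceleration and heart rate.

The study's own sleep algorithm is unspecified, so this module implements a
transparent actigraphy-style stand-in: a minute is quiescent when both the
acceleration magnitude and the heart rate fall below participant-adaptive
thresholds (the midpoint of each channel's 20th and 80th percentile); short
gaps are closed, blips removed, and the longest quiescent run per night
(noon-to-noon window) of at least three hours becomes that night's single
main sleep period, snapped to 1-min resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import InsufficientDataError, RunConfig

# channels with less dynamic range than this between their 20th and 80th
# percentiles carry no sleep/wake signal (e.g. constant activity)
_MIN_RANGE = {"acc": 0.005, "hr": 3.0}


@dataclass(frozen=True)
class SleepPeriod:
    onset: pd.Timestamp
    wake: pd.Timestamp

    @property
    def duration_hours(self) -> float:
        return (self.wake - self.onset) / pd.Timedelta(hours=1)


class SleepSchedule:
    """Per-night main sleep periods for one participant.

    Onset/wake clock positions are measured in hours from the noon preceding
    each night (23:00 -> 11.0, 00:30 -> 12.5, 07:00 wake -> 19.0) so that
    averages across nights are well defined without wrap-around.
    """

    def __init__(self, periods: list[SleepPeriod]):
        self.periods = sorted(periods, key=lambda p: p.onset)
        for a, b in zip(self.periods, self.periods[1:]):
            if b.onset < a.wake:
                raise ValueError("overlapping sleep periods")

    def __len__(self) -> int:
        return len(self.periods)

    @staticmethod
    def _noon_anchor(t: pd.Timestamp) -> pd.Timestamp:
        noon = t.normalize() + pd.Timedelta(hours=12)
        return noon if t >= noon else noon - pd.Timedelta(days=1)

    def onset_hours(self) -> np.ndarray:
        return np.array([(p.onset - self._noon_anchor(p.onset))
                         / pd.Timedelta(hours=1) for p in self.periods])

    def wake_hours(self) -> np.ndarray:
        return np.array([(p.wake - self._noon_anchor(p.onset))
                         / pd.Timedelta(hours=1) for p in self.periods])

    def mean_onset_hour(self) -> float:
        return float(self.onset_hours().mean())

    def mean_wake_hour(self) -> float:
        return float(self.wake_hours().mean())

    def last_completed_before(self, t: pd.Timestamp) -> SleepPeriod | None:
        """Most recent sleep period fully completed (woken) before ``t``."""
        done = [p for p in self.periods if p.wake <= t]
        return done[-1] if done else None

    def covering(self, t: pd.Timestamp) -> SleepPeriod | None:
        for p in self.periods:
            if p.onset <= t < p.wake:
                return p
        return None


def _minute_means(series: pd.Series) -> pd.Series:
    return series.resample("1min").mean()


def _adaptive_threshold(values: np.ndarray, quantiles, min_range: float):
    """Midpoint of the low/high quantiles, or None if the channel has too
    little dynamic range to separate sleep from wake."""
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return None
    lo, hi = np.quantile(finite, quantiles)
    if hi - lo < min_range:
        return None
    return 0.5 * (lo + hi)


def estimate_sleep_wake(acc: pd.Series, hr: pd.Series,
                        config: RunConfig | None = None) -> SleepSchedule:
    """Detect one main sleep period per night from acc + HR minute profiles.

    Raises
    ------
    InsufficientDataError
        If the recording spans less than 24 h.
    """
    config = config or RunConfig()
    span = acc.index[-1] - acc.index[0]
    if span < pd.Timedelta(hours=24):
        raise InsufficientDataError(
            f"sleep estimation needs >= 24 h of data, got {span}")

    acc_m = _minute_means(acc)
    hr_m = _minute_means(hr).reindex(acc_m.index)

    q = config.sleep_acc_quantiles
    acc_thr = _adaptive_threshold(acc_m.to_numpy(), q, _MIN_RANGE["acc"])
    hr_thr = _adaptive_threshold(hr_m.to_numpy(), q, _MIN_RANGE["hr"])
    if acc_thr is None and hr_thr is None:
        return SleepSchedule([])

    quiescent = np.ones(len(acc_m), dtype=bool)
    if acc_thr is not None:
        quiescent &= acc_m.to_numpy() <= acc_thr
    if hr_thr is not None:
        with np.errstate(invalid="ignore"):
            quiescent &= hr_m.to_numpy() <= hr_thr
    quiescent &= np.isfinite(acc_m.to_numpy())

    # close sensor-gap sized holes, then drop sub-5-min blips
    gap = config.sleep_gap_minutes
    quiescent = ndimage.binary_closing(quiescent, structure=np.ones(gap + 1))
    quiescent = ndimage.binary_opening(quiescent, structure=np.ones(5))

    index = acc_m.index
    periods: list[SleepPeriod] = []
    first_noon = SleepSchedule._noon_anchor(index[0])
    n_nights = int(np.ceil((index[-1] - first_noon)
                           / pd.Timedelta(days=1)))
    for night in range(n_nights):
        w0 = first_noon + pd.Timedelta(days=night)
        w1 = w0 + pd.Timedelta(days=1)
        sel = (index >= w0) & (index < w1)
        best = _longest_run(quiescent & sel)
        if best is None:
            continue
        i0, i1 = best
        if (i1 - i0) < config.sleep_min_minutes:
            continue
        periods.append(SleepPeriod(onset=index[i0],
                                   wake=index[i1 - 1] + pd.Timedelta(minutes=1)))
    return SleepSchedule(periods)


def _longest_run(flags: np.ndarray) -> tuple[int, int] | None:
    """(start, stop) of the longest True run, or None."""
    if not flags.any():
        return None
    padded = np.concatenate(([False], flags, [False]))
    d = np.diff(padded.astype(int))
    starts = np.nonzero(d == 1)[0]
    stops = np.nonzero(d == -1)[0]
    k = int(np.argmax(stops - starts))
    return int(starts[k]), int(stops[k])
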