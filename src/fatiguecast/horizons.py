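"""The five aggregation windows anchored to one fatigue rating.

For a rating at time t with the most recent completed sleep (onset, wake):

* ``1h``/``3h``/``6h``: [max(t - h, wake), t) — the backward-looking windows
  never reach into sleep, so a rating less than one hour after waking makes
  the 1h, 3h, 6h and awake windows identical, and a rating between one and
  three hours after waking makes 3h, 6h and awake identical.
* ``aw``: [wake, t), time since waking.
* ``as``: [onset, wake), the most recent completed sleep period; unavailable
  when no completed sleep precedes the rating.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import HORIZONS
from .sleep import SleepSchedule

Interval = tuple[pd.Timestamp, pd.Timestamp]


@dataclass(frozen=True)
class TimeHorizons:
    rating_time: pd.Timestamp
    windows: dict  # name -> (start, end) or None

    def __getitem__(self, name: str) -> Interval | None:
        return self.windows[name]

    def available(self) -> list[str]:
        return [h for h in HORIZONS if self.windows[h] is not None]


def build_horizons(rating_time: pd.Timestamp,
                   schedule: SleepSchedule,
                   horizon_hours=(1, 3, 6)) -> TimeHorizons:
    """Build the five windows for one rating.

    With no completed sleep before the rating, the asleep and awake windows
    are marked unavailable and the hour windows are plain lookbacks.
    """
    sleep = schedule.last_completed_before(rating_time)
    windows: dict = {}
    if sleep is None:
        windows["as"] = None
        windows["aw"] = None
        wake = None
    else:
        windows["as"] = (sleep.onset, sleep.wake)
        windows["aw"] = (sleep.wake, rating_time)
        wake = sleep.wake
    for h in horizon_hours:
        start = rating_time - pd.Timedelta(hours=h)
        if wake is not None:
            start = max(start, wake)
        windows[f"{h}h"] = (start, rating_time)
    return TimeHorizons(rating_time=rating_time, windows=windows)
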