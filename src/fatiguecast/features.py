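"""Per-rating feature extraction across the five time horizons.

Feature naming encodes (signal, horizon, statistic), e.g. ``sdnn_3h_min``,
``sd2_as_sd``, ``act_aw_int``, ``edapeaks_1h_sd``.  Horizon codes are ``1h``,
``3h``, ``6h``, ``aw`` (since waking) and ``as`` (previous sleep period).

Cardiac variability is only ever computed inside 5-min rest windows: no
measurable continuous arm motion (population SD of acceleration magnitude
below a threshold), mean heart rate below 55% of the age-predicted maximum
(220 - age), and fewer than 4 artifact beats (which are repaired by linear
interpolation).  Windows live on a 5-min grid anchored to local midnight and
clipped to each horizon, so overlapping horizons of nearby ratings see
identical windows.

Slope statistics are ordinary least-squares coefficients in units per hour:
for HR/EDA/skin temperature over 1-min means, for HRV metrics over one value
per accepted rest window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from . import hrv
from .config import HORIZONS, RunConfig, feature_group
from .horizons import TimeHorizons, build_horizons
from .io import FeatureTable, SensorBundle
from .sleep import SleepSchedule

_H_PER_NS = 1.0 / 3.6e12

HRV_SIGNALS = ("sdnn", "sd1", "sd2")
BASIC_STATS = ("min", "max", "mean", "sd", "slope")


def _hours(index: pd.DatetimeIndex) -> np.ndarray:
    return index.asi8 * _H_PER_NS


def _ts_hours(ts: pd.Timestamp) -> float:
    return ts.value * _H_PER_NS


# ---------------------------------------------------------------------------
# aggregation primitives
# ---------------------------------------------------------------------------

def aggregate_stats(times_h: np.ndarray, values: np.ndarray) -> dict:
    """min/max/mean/sd/slope of a (time, value) series.

    ``times_h`` in hours; the slope is the OLS coefficient in units/hour.
    With no values everything is NaN; with one value the slope is NaN and
    the population SD is 0.
    """
    t = np.asarray(times_h, dtype=float)
    v = np.asarray(values, dtype=float)
    keep = np.isfinite(v) & np.isfinite(t)
    t, v = t[keep], v[keep]
    out = {s: np.nan for s in BASIC_STATS}
    if v.size == 0:
        return out
    out["min"] = float(v.min())
    out["max"] = float(v.max())
    out["mean"] = float(v.mean())
    out["sd"] = float(v.std())
    if v.size >= 2:
        tc = t - t.mean()
        denom = float(tc @ tc)
        out["slope"] = float(tc @ (v - v.mean()) / denom) if denom > 0 else np.nan
    return out


# ---------------------------------------------------------------------------
# rest windows and HRV
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RestWindow:
    """One accepted 5-min low-motion rest window with cleaned beats."""

    start: pd.Timestamp
    end: pd.Timestamp
    ibis: np.ndarray
    n_interpolated: int
    metrics: hrv.HRVMetrics

    @property
    def center_hours(self) -> float:
        return 0.5 * (_ts_hours(self.start) + _ts_hours(self.end))


def _cell_sums(times_h, values, edges_h):
    """Per-cell count, nan-count, sum and sum of squares via cumsums."""
    v = np.asarray(values, dtype=float)
    isnan = ~np.isfinite(v)
    v0 = np.where(isnan, 0.0, v)
    cs = np.concatenate(([0.0], np.cumsum(v0)))
    cs2 = np.concatenate(([0.0], np.cumsum(v0 * v0)))
    csn = np.concatenate(([0], np.cumsum(isnan)))
    i0 = np.searchsorted(times_h, edges_h[:-1], side="left")
    i1 = np.searchsorted(times_h, edges_h[1:], side="left")
    n = i1 - i0
    return n, csn[i1] - csn[i0], cs[i1] - cs[i0], cs2[i1] - cs2[i0]


def max_rest_hr(age: float, fraction: float = 0.55) -> float:
    """Rest criterion: mean HR must stay below fraction * (220 - age)."""
    return fraction * (220.0 - age)


def rest_window_grid(hr: pd.Series, acc: pd.Series, ibi: pd.Series,
                     age: float, config: RunConfig) -> list[RestWindow]:
    """All accepted rest windows over the full recording, on the 5-min grid
    anchored at local midnight."""
    t_acc = _hours(acc.index)
    t_hr = _hours(hr.index)
    anchor = acc.index[0].normalize()
    step_h = config.rest_window_minutes / 60.0
    start_h = _ts_hours(anchor)
    end_h = max(t_acc[-1], t_hr[-1]) if t_acc.size and t_hr.size else start_h
    n_cells = int(np.ceil((end_h - start_h) / step_h))
    if n_cells <= 0:
        return []
    edges = start_h + step_h * np.arange(n_cells + 1)

    n_a, nan_a, s_a, s2_a = _cell_sums(t_acc, acc.to_numpy(), edges)
    n_h, nan_h, s_h, _ = _cell_sums(t_hr, hr.to_numpy(), edges)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_a = s_a / n_a
        var_a = np.maximum(s2_a / n_a - mean_a ** 2, 0.0)
        sd_a = np.sqrt(var_a)
        mean_hr = s_h / n_h

    hr_limit = max_rest_hr(age, config.rest_hr_fraction)
    eligible = ((n_a >= 3) & (nan_a == 0) & (sd_a < config.motion_sd_threshold)
                & (n_h >= 1) & (nan_h == 0) & (mean_hr < hr_limit))

    t_ibi = _hours(ibi.index)
    v_ibi = ibi.to_numpy(dtype=float)
    windows: list[RestWindow] = []
    for c in np.nonzero(eligible)[0]:
        j0 = np.searchsorted(t_ibi, edges[c], side="left")
        j1 = np.searchsorted(t_ibi, edges[c + 1], side="left")
        raw = v_ibi[j0:j1]
        try:
            cleaned, n_interp = hrv.clean_with_flags(
                raw, dev_fraction=config.artifact_dev_fraction,
                max_interpolated=config.max_interpolated_ibis,
                min_ibis=config.min_window_ibis)
        except hrv.WindowRejected:
            continue
        start = anchor + pd.Timedelta(minutes=config.rest_window_minutes * c)
        windows.append(RestWindow(
            start=start, end=start + pd.Timedelta(
                minutes=config.rest_window_minutes),
            ibis=cleaned, n_interpolated=n_interp,
            metrics=hrv.poincare_metrics(cleaned, config.min_window_ibis)))
    return windows


def detect_rest_windows(hr: pd.Series, acc: pd.Series, ibi: pd.Series,
                        age: float, horizon,
                        config: RunConfig | None = None) -> list[RestWindow]:
    """Accepted rest windows whose 5-min cell lies fully inside ``horizon``."""
    config = config or RunConfig()
    start, end = horizon
    grid = rest_window_grid(hr, acc, ibi, age, config)
    return [w for w in grid if w.start >= start and w.end <= end]


def _windows_in(grid: list[RestWindow], interval) -> list[RestWindow]:
    start, end = interval
    return [w for w in grid if w.start >= start and w.end <= end]


# ---------------------------------------------------------------------------
# electrodermal activity
# ---------------------------------------------------------------------------

def phasic_eda(eda: pd.Series, config: RunConfig | None = None) -> pd.Series:
    """High-pass the EDA signal to isolate skin-conductance responses.

    Uses a second-order Butterworth high-pass at ``eda_highpass_hz`` when the
    sampling rate supports it; at slower rates (e.g. 1-min test data) the
    tonic level is removed by subtracting a 10-min rolling minimum instead.
    NaN gaps stay NaN; segments shorter than 10 samples are left NaN.
    """
    config = config or RunConfig()
    values = eda.to_numpy(dtype=float)
    out = np.full_like(values, np.nan)
    if len(eda) >= 2:
        dt_s = (eda.index[1] - eda.index[0]) / pd.Timedelta(seconds=1)
    else:
        dt_s = 1.0
    fs = 1.0 / dt_s
    use_butter = config.eda_highpass_hz < 0.45 * (fs / 2.0)

    finite = np.isfinite(values)
    bounds = np.nonzero(np.diff(np.concatenate(
        ([False], finite, [False])).astype(int)))[0].reshape(-1, 2)
    for a, b in bounds:
        seg = values[a:b]
        if seg.size < 10:
            continue
        if use_butter:
            sos = sp_signal.butter(2, config.eda_highpass_hz, "highpass",
                                   fs=fs, output="sos")
            out[a:b] = sp_signal.sosfiltfilt(sos, seg)
        else:
            w = max(3, int(round(600.0 / dt_s)))
            baseline = (pd.Series(seg).rolling(w, min_periods=1, center=True)
                        .min().to_numpy())
            out[a:b] = seg - baseline
    return pd.Series(out, index=eda.index)


def eda_peak_times(eda: pd.Series,
                   config: RunConfig | None = None) -> pd.DatetimeIndex:
    """Times of skin-conductance-response peaks over the whole series: local
    maxima of the phasic signal with prominence >= ``eda_prominence``."""
    config = config or RunConfig()
    ph = phasic_eda(eda, config)
    v = ph.to_numpy()
    v_filled = np.where(np.isfinite(v), v, -np.inf)
    idx, _ = sp_signal.find_peaks(v_filled, prominence=config.eda_prominence)
    idx = idx[np.isfinite(v[idx])]
    return eda.index[idx]


def count_eda_peaks(eda: pd.Series, horizon,
                    config: RunConfig | None = None) -> tuple[int, np.ndarray]:
    """Peak count within ``horizon`` plus counts per full 5-min subwindow
    (the latter feed the 'sd of peak counts' feature)."""
    config = config or RunConfig()
    start, end = horizon
    peaks = eda_peak_times(eda, config)
    t = _hours(peaks)
    h0, h1 = _ts_hours(start), _ts_hours(end)
    total = int(np.sum((t >= h0) & (t < h1)))
    step_h = config.rest_window_minutes / 60.0
    n_bins = int(np.floor((h1 - h0) / step_h))
    if n_bins == 0:
        return total, np.array([])
    edges = h0 + step_h * np.arange(n_bins + 1)
    counts, _ = np.histogram(t, bins=edges)
    return total, counts


# ---------------------------------------------------------------------------
# physical activity
# ---------------------------------------------------------------------------

def activity_features(acc: pd.Series, steps: pd.DataFrame, horizon) -> dict:
    """Acceleration-magnitude stats, the trapezoidal integral of magnitude
    (acceleration-hours), and the step sum with interval proration at the
    horizon edges."""
    start, end = horizon
    h0, h1 = _ts_hours(start), _ts_hours(end)
    t = _hours(acc.index)
    sel = (t >= h0) & (t < h1)
    stats = aggregate_stats(t[sel], acc.to_numpy()[sel])
    out = {f"act_{s}": stats[s] for s in ("mean", "min", "max", "sd")}

    tv, vv = t[sel], acc.to_numpy()[sel]
    keep = np.isfinite(vv)
    if keep.sum() >= 2:
        out["act_int"] = float(np.trapezoid(vv[keep], tv[keep]))
    else:
        out["act_int"] = np.nan

    if len(steps):
        s0 = _hours(pd.DatetimeIndex(steps["start"]))
        s1 = _hours(pd.DatetimeIndex(steps["end"]))
        counts = steps["steps"].to_numpy(dtype=float)
        overlap = np.clip(np.minimum(s1, h1) - np.maximum(s0, h0), 0.0, None)
        width = s1 - s0
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(width > 0, overlap / width, 0.0)
        out["steps_count"] = float(np.sum(counts * frac))
    else:
        out["steps_count"] = np.nan
    return out


# ---------------------------------------------------------------------------
# routine and weather
# ---------------------------------------------------------------------------

def routine_features(rating_time: pd.Timestamp,
                     schedule: SleepSchedule) -> dict:
    """Time of day (hours), time awake, previous-night sleep duration and
    the deviations of that night's bed/wake times from the participant's
    study-mean bed/wake times (hours; positive = later than usual)."""
    out = {f: np.nan for f in ("time_of_day", "time_awake", "sleep_duration",
                               "wake_dev", "bed_dev")}
    midnight = rating_time.normalize()
    out["time_of_day"] = (rating_time - midnight) / pd.Timedelta(hours=1)
    sleep = schedule.last_completed_before(rating_time)
    if sleep is None or len(schedule) == 0:
        return out
    out["time_awake"] = (rating_time - sleep.wake) / pd.Timedelta(hours=1)
    out["sleep_duration"] = sleep.duration_hours
    k = schedule.periods.index(sleep)
    out["wake_dev"] = float(schedule.wake_hours()[k]
                            - schedule.mean_wake_hour())
    out["bed_dev"] = float(schedule.onset_hours()[k]
                           - schedule.mean_onset_hour())
    return out


WEATHER_FEATURES = {
    "wea_temp_mean": "temp_mean",
    "wea_temp_min": "temp_min",
    "wea_tempfelt_min": "temp_felt_min",
    "wea_dew_mean": "dew_mean",
    "wea_hum_mean": "humidity_mean",
}


def weather_features(weather: pd.DataFrame, rating_date) -> dict:
    """Day-level weather copied to every rating of that day; a missing day
    masks all weather features."""
    row = weather.loc[weather["date"] == rating_date]
    if row.empty:
        return {f: np.nan for f in WEATHER_FEATURES}
    row = row.iloc[0]
    return {f: float(row[c]) for f, c in WEATHER_FEATURES.items()}


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def feature_names(config: RunConfig | None = None) -> list[str]:
    """The full feature census, in emission order."""
    names: list[str] = []
    for sig in ("hr",) + HRV_SIGNALS + ("eda", "skintemp"):
        for hz in HORIZONS:
            names += [f"{sig}_{hz}_{s}" for s in BASIC_STATS]
    for hz in HORIZONS:
        names += [f"edapeaks_{hz}_count", f"edapeaks_{hz}_sd"]
    for hz in HORIZONS:
        names += [f"act_{hz}_{s}" for s in ("mean", "min", "max", "sd", "int")]
        names += [f"steps_{hz}_count"]
    names += ["time_of_day", "time_awake", "sleep_duration",
              "wake_dev", "bed_dev"]
    names += list(WEATHER_FEATURES)
    return names


def assemble_features(bundle: SensorBundle, ratings: pd.DataFrame,
                      schedule: SleepSchedule, weather: pd.DataFrame,
                      age: float, config: RunConfig | None = None,
                      participant_id: str | None = None) -> FeatureTable:
    """One feature vector per rating for a single participant.

    Ratings that fall inside a detected sleep period are excluded with a
    warning.  Missing values (no rest window in a horizon, EDA gaps, no
    prior night, missing weather day) are NaN in the value frame and False
    in the mask.
    """
    config = config or RunConfig()
    pid = participant_id or bundle.participant_id
    grid = rest_window_grid(bundle.hr, bundle.acc, bundle.ibi, age, config)
    peak_times = eda_peak_times(bundle.eda, config)
    peak_hours = _hours(peak_times)

    minute = {ch: series.resample("1min").mean()
              for ch, series in bundle.channels().items()}
    minute_hours = {ch: _hours(s.index) for ch, s in minute.items()}
    minute_vals = {ch: s.to_numpy(dtype=float) for ch, s in minute.items()}

    channel_prefix = {"hr": "hr", "eda": "eda", "temp": "skintemp"}
    rows, kept = [], []
    for rec in ratings.itertuples(index=False):
        t = rec.timestamp
        if schedule.covering(t) is not None:
            warnings.warn(
                f"rating {rec.rating_id} at {t} falls inside detected sleep;"
                " excluded")
            continue
        horizons = build_horizons(t, schedule, config.horizon_hours)
        feats: dict[str, float] = {}
        for hz in HORIZONS:
            interval = horizons[hz]
            if interval is None:
                for sig in ("hr",) + HRV_SIGNALS + ("eda", "skintemp"):
                    for s in BASIC_STATS:
                        feats[f"{sig}_{hz}_{s}"] = np.nan
                feats[f"edapeaks_{hz}_count"] = np.nan
                feats[f"edapeaks_{hz}_sd"] = np.nan
                for s in ("mean", "min", "max", "sd", "int"):
                    feats[f"act_{hz}_{s}"] = np.nan
                feats[f"steps_{hz}_count"] = np.nan
                continue
            h0, h1 = (_ts_hours(interval[0]), _ts_hours(interval[1]))
            # uniform channels over 1-min means
            for ch, prefix in channel_prefix.items():
                th, vh = minute_hours[ch], minute_vals[ch]
                sel = (th >= h0) & (th < h1)
                stats = aggregate_stats(th[sel], vh[sel])
                for s in BASIC_STATS:
                    feats[f"{prefix}_{hz}_{s}"] = stats[s]
            # HRV over rest windows
            wins = _windows_in(grid, interval)
            centers = np.array([w.center_hours for w in wins])
            for sig in HRV_SIGNALS:
                vals = np.array([getattr(w.metrics, sig) for w in wins])
                stats = aggregate_stats(centers, vals)
                for s in BASIC_STATS:
                    feats[f"{sig}_{hz}_{s}"] = stats[s]
            # EDA peaks (missing when the EDA channel is fully gapped)
            eda_sel = ((minute_hours["eda"] >= h0)
                       & (minute_hours["eda"] < h1))
            if np.isfinite(minute_vals["eda"][eda_sel]).any():
                n_pk = int(np.sum((peak_hours >= h0) & (peak_hours < h1)))
                feats[f"edapeaks_{hz}_count"] = float(n_pk)
                step_h = config.rest_window_minutes / 60.0
                n_bins = int(np.floor((h1 - h0) / step_h))
                if n_bins > 0:
                    edges = h0 + step_h * np.arange(n_bins + 1)
                    counts, _ = np.histogram(peak_hours, bins=edges)
                    feats[f"edapeaks_{hz}_sd"] = float(counts.std())
                else:
                    feats[f"edapeaks_{hz}_sd"] = np.nan
            else:
                feats[f"edapeaks_{hz}_count"] = np.nan
                feats[f"edapeaks_{hz}_sd"] = np.nan
            feats.update({f"{k.split('_')[0]}_{hz}_{k.split('_', 1)[1]}": v
                          for k, v in activity_features(
                              bundle.acc, bundle.steps, interval).items()})
        feats.update(routine_features(t, schedule))
        feats.update(weather_features(weather, t.date()))
        rows.append(feats)
        kept.append(rec)

    names = feature_names(config)
    data = pd.DataFrame(rows, columns=names) if rows else pd.DataFrame(
        columns=names)
    meta = pd.DataFrame({
        "rating_id": [r.rating_id for r in kept],
        "participant_id": pid,
        "rating_time": [r.timestamp for r in kept],
        "vas": [r.vas for r in kept],
    })
    df = pd.concat([meta.reset_index(drop=True),
                    data.reset_index(drop=True)], axis=1)
    mask = data.notna()
    groups = {f: feature_group(f, config.feature_groups) for f in names}
    return FeatureTable(df, mask, groups)
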