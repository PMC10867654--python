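"""Seeded synthetic cohorts with known ground truth.

The generator emulates the study conditions: two-week wrist recordings for
three subgroups (healthy controls; MS with functional ANS; MS with
dysfunctional ANS), roughly 3.8 momentary fatigue ratings per participant
per day, group-specific feature effects with published directions, a daily
upward fatigue trend (via the time-of-day/time-awake effects) and about a
quarter of feature vectors incomplete — preferentially missing cardiac
features, because gaps are injected as motion bursts in the hour before a
rating.

Generation is two-stage: raw streams are synthesized first, the pipeline's
own extractor turns them into per-rating features, and ratings are then
produced from a known additive model over the *normalized extracted*
features plus Gaussian noise.  Computing ratings from extracted rather than
hidden stream parameters removes extractor/generator mismatch as a
confounder in recovery tests: at zero noise a rating is an exact function of
the stored truth features.

Physiological realism stops at second-order statistics: IBIs are AR(1)
Gaussian (marginal SD = SDNN target, lag-1 correlation set by the SD1
target), EDA is a tonic baseline plus Poisson-timed exponential-decay
responses, acceleration is bounded activity bouts over a quiet floor, and
skin temperature a slow sinusoid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import timedelta, timezone

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from . import features as fx
from . import preprocess
from .config import Group, ParameterError, RunConfig, Sex
from .io import FeatureTable, SensorBundle
from .sleep import SleepPeriod, SleepSchedule, estimate_sleep_wake

_START = "2021-03-01 12:00"         # fixed local start (noon) for determinism


# ---------------------------------------------------------------------------
# specs and truth
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Cohort dimensions and noise; defaults are the emulated study
    conditions (14 days, ~3.8 ratings/day, 25% incomplete vectors)."""

    n_co: int = 23
    n_ms1: int = 27
    n_ms2: int = 24
    days: int = 14
    ratings_per_day: float = 3.8
    missing_rate: float = 0.25
    noise_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_co, self.n_ms1, self.n_ms2) < 0 or self.days < 1:
            raise ParameterError("counts must be >= 0 and days >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ParameterError("missing_rate must lie in [0, 1)")


@dataclass(frozen=True)
class Effect:
    """One bounded ground-truth partial effect on the latent fatigue."""

    feature: str
    shape: str            # rise | fall | arch | dip | linear
    amplitude: float

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        a = self.amplitude
        if self.shape == "rise":
            return a * np.tanh(1.2 * x)
        if self.shape == "fall":
            return -a * np.tanh(1.2 * x)
        if self.shape == "arch":
            return a * np.exp(-0.5 * x * x)
        if self.shape == "dip":
            return -a * np.exp(-0.5 * x * x)
        if self.shape == "linear":
            return a * x
        raise ParameterError(f"unknown effect shape {self.shape!r}")


@dataclass
class TruthModel:
    """Per-group ground-truth effect sets plus the latent noise SD."""

    effects: dict[str, list[Effect]]
    noise_sd: float = 0.8

    def validate(self) -> None:
        known = set(fx.feature_names())
        bad = [e.feature for effs in self.effects.values()
               for e in effs if e.feature not in known]
        if bad:
            raise ParameterError(
                f"truth references features the extractor does not "
                f"produce: {sorted(set(bad))}")

    def features(self) -> list[str]:
        seen: list[str] = []
        for effs in self.effects.values():
            for e in effs:
                if e.feature not in seen:
                    seen.append(e.feature)
        return seen

    def to_record(self, grid=None) -> dict:
        grid = np.linspace(-2.5, 2.5, 21) if grid is None else np.asarray(grid)
        return {
            "noise_sd": self.noise_sd,
            "grid": grid.tolist(),
            "effects": {
                g: [{"feature": e.feature, "shape": e.shape,
                     "amplitude": e.amplitude, "values": e(grid).tolist()}
                    for e in effs]
                for g, effs in self.effects.items()},
        }


def default_truth(noise_sd: float = 0.8) -> TruthModel:
    """Group-specific effects following the published direction structure:
    routine drives everyone (time of day for controls and MS II, time awake
    and short sleep for MS I), cardiac effects flip sign with ANS status,
    and activity/weather contribute smaller effects."""
    co = [
        Effect("time_of_day", "rise", 0.55),
        Effect("hr_6h_mean", "rise", 0.30),
        Effect("sdnn_6h_mean", "rise", 0.30),
        Effect("sd1_aw_mean", "fall", 0.30),
        Effect("sd2_as_min", "rise", 0.25),
        Effect("sdnn_as_min", "arch", 0.30),
        Effect("edapeaks_as_sd", "fall", 0.25),
        Effect("steps_6h_count", "fall", 0.25),
        Effect("act_aw_max", "fall", 0.25),
        Effect("wea_dew_mean", "fall", 0.20),
    ]
    ms1 = [
        Effect("time_awake", "rise", 0.55),
        Effect("sleep_duration", "fall", 0.30),
        Effect("hr_as_slope", "rise", 0.25),
        Effect("sd2_aw_sd", "rise", 0.30),
        Effect("sdnn_aw_max", "fall", 0.30),
        Effect("act_as_max", "rise", 0.25),
        Effect("steps_6h_count", "fall", 0.25),
        Effect("wea_temp_mean", "fall", 0.20),
        Effect("wea_tempfelt_min", "rise", 0.20),
    ]
    ms2 = [
        Effect("time_of_day", "rise", 0.55),
        Effect("hr_as_mean", "rise", 0.30),
        Effect("sd1_3h_mean", "rise", 0.30),
        Effect("sd2_as_sd", "rise", 0.25),
        Effect("sdnn_1h_sd", "rise", 0.30),
        Effect("edapeaks_1h_sd", "rise", 0.25),
        Effect("steps_aw_count", "rise", 0.25),
        Effect("wea_hum_mean", "rise", 0.20),
    ]
    truth = TruthModel(effects={Group.CO.value: co, Group.MS_I.value: ms1,
                                Group.MS_II.value: ms2},
                       noise_sd=noise_sd)
    truth.validate()
    return truth


# ---------------------------------------------------------------------------
# channel generators
# ---------------------------------------------------------------------------

def generate_ibi_series(profile: dict, duration_s: float, seed,
                        start=None, tz_hours: int = 1) -> pd.Series:
    """AR(1) Gaussian inter-beat intervals hitting SDNN/SD1 targets.

    ``profile`` needs ``mean_ibi_ms``, ``sdnn_ms``, ``sd1_ms``.  The AR(1)
    lag-1 correlation is 1 - (sd1/sdnn)^2, which reproduces both targets in
    expectation; the pair is infeasible when sd1 > sdnn * sqrt(2).
    """
    mu = float(profile["mean_ibi_ms"])
    s = float(profile["sdnn_ms"])
    sd1 = float(profile["sd1_ms"])
    if mu <= 0:
        raise ParameterError("mean_ibi_ms must be positive")
    if s < 0 or sd1 < 0:
        raise ParameterError("SD targets must be >= 0")
    tz = timezone(timedelta(hours=tz_hours))
    start = pd.Timestamp(_START, tz=tz) if start is None else start
    if duration_s <= 0:
        return pd.Series(np.array([]), index=pd.DatetimeIndex([], tz=tz),
                         name="ibi_ms")
    rng = np.random.default_rng(seed)
    n = int(np.ceil(duration_s * 1000.0 / mu * 1.2)) + 10
    if s == 0:
        ibis = np.full(n, mu)
    else:
        rho = 1.0 - (sd1 / s) ** 2
        if rho <= -1.0:
            raise ParameterError(
                f"infeasible targets: sd1 {sd1} > sdnn*sqrt(2) = {s * np.sqrt(2):.3g}")
        e = rng.standard_normal(n) * s * np.sqrt(max(1.0 - rho ** 2, 1e-12))
        dev = sp_signal.lfilter([1.0], [1.0, -rho], e)
        dev[0] = rng.standard_normal() * s
        ibis = np.maximum(mu + dev, 0.2 * mu)
    t_s = np.cumsum(ibis) / 1000.0
    keep = t_s <= duration_s
    index = start + pd.to_timedelta(t_s[keep], unit="s")
    return pd.Series(ibis[keep], index=index, name="ibi_ms")


def _scr_kernel(dt_s: float) -> np.ndarray:
    """Skin-conductance-response kernel: short rise, ~2.5 min decay."""
    rise_n = max(1, int(round(60.0 / dt_s)))
    decay_t = np.arange(0, 600.0, dt_s)
    kernel = np.concatenate([np.linspace(0.4, 1.0, rise_n),
                             np.exp(-decay_t / 150.0)])
    return kernel


@dataclass
class _Streams:
    """Intermediate per-participant simulation state."""

    bundle: SensorBundle
    schedule: SleepSchedule
    bouts: list[tuple[pd.Timestamp, pd.Timestamp, float]]


def _simulate_participant(pid: str, age: float, spec: CohortSpec,
                          config: RunConfig, seed_seq) -> _Streams:
    rng = np.random.default_rng(seed_seq)
    tz = timezone(timedelta(hours=config.utc_offset_hours))
    start = pd.Timestamp(_START, tz=tz)
    n_days = spec.days + 1          # one extra night before the first day
    end = start + pd.Timedelta(days=n_days)
    dt_s = 1.0 / config.sampling_rate_hz
    index = pd.date_range(start, end, freq=pd.Timedelta(seconds=dt_s),
                          inclusive="left")
    t_h = index.asi8 / 3.6e12
    n = len(index)

    # -- true sleep schedule ------------------------------------------------
    periods = []
    for night in range(n_days):
        onset_h = float(np.clip(rng.normal(11.0, 0.7), 9.5, 13.0))
        dur_h = float(np.clip(rng.normal(8.0, 0.8), 6.0, 10.0))
        onset = start + pd.Timedelta(days=night, hours=onset_h)
        wake = onset + pd.Timedelta(hours=dur_h)
        periods.append(SleepPeriod(onset=onset.floor("min"),
                                   wake=wake.floor("min")))
    schedule = SleepSchedule(periods)

    asleep = np.zeros(n, dtype=bool)
    h0 = t_h[0]
    for p in periods:
        a = int((p.onset.value / 3.6e12 - h0) * 3600.0 / dt_s)
        b = int((p.wake.value / 3.6e12 - h0) * 3600.0 / dt_s)
        asleep[max(a, 0):min(b, n)] = True

    # -- activity bouts ------------------------------------------------------
    bouts = []
    bout_level = np.zeros(n)
    for night in range(n_days):
        wake_t = periods[night - 1].wake if night > 0 else start
        onset_t = periods[night].onset
        if onset_t <= wake_t:
            continue
        for _ in range(rng.poisson(5)):
            dur_min = rng.uniform(10, 40)
            t0 = wake_t + pd.Timedelta(
                hours=rng.uniform(0, max((onset_t - wake_t)
                                         / pd.Timedelta(hours=1) - dur_min / 60,
                                         0.01)))
            t1 = t0 + pd.Timedelta(minutes=dur_min)
            intensity = rng.uniform(0.3, 1.0)
            a = int((t0.value / 3.6e12 - h0) * 3600.0 / dt_s)
            b = int((t1.value / 3.6e12 - h0) * 3600.0 / dt_s)
            bout_level[max(a, 0):min(b, n)] = np.maximum(
                bout_level[max(a, 0):min(b, n)], intensity)
            bouts.append((t0, t1, intensity))
    bout_level[asleep] = 0.0

    # -- acceleration magnitude ---------------------------------------------
    base = np.where(asleep, 0.010, 0.030)
    quiet_noise = np.abs(rng.normal(0.0, 0.004, n)) * np.where(asleep, 0.5, 1.0)
    bout_noise = bout_level * np.abs(rng.normal(1.0, 0.35, n))
    acc = base + quiet_noise + bout_noise

    # -- heart rate ----------------------------------------------------------
    smooth_bout = sp_signal.lfilter([0.2], [1.0, -0.8], bout_level)
    hr_clean = np.where(asleep, 54.0, 70.0) + 18.0 * smooth_bout
    hr_clean += 1.5 * np.sin(2 * np.pi * (t_h - t_h[0]) / 24.0)
    hr = hr_clean + rng.normal(0.0, 1.2, n)

    # -- electrodermal activity ---------------------------------------------
    tod = np.mod(t_h + config.utc_offset_hours, 24.0)
    tonic = 2.0 + 0.3 * np.sin(2 * np.pi * (tod - 8.0) / 24.0)
    rate_per_sample = np.where(asleep, 0.05, 0.25) * dt_s / 60.0
    events = rng.random(n) < rate_per_sample
    amps = np.where(events, rng.lognormal(np.log(0.22), 0.5, n), 0.0)
    phasic = np.convolve(amps, _scr_kernel(dt_s))[:n]
    eda = tonic + phasic + rng.normal(0.0, 0.008, n)

    # -- skin temperature ----------------------------------------------------
    temp = (33.0 + 0.6 * np.sin(2 * np.pi * (tod - 16.0) / 24.0)
            + 0.4 * asleep + rng.normal(0.0, 0.05, n))

    # -- inter-beat intervals ------------------------------------------------
    mean_ibi = 60000.0 / hr_clean
    sd_t = np.where(asleep, 55.0, 40.0)
    rho = 0.5
    n_beats = int(np.ceil(n_days * 86400.0 * 1000.0 / mean_ibi.min() * 1.05))
    e = rng.standard_normal(n_beats) * np.sqrt(1.0 - rho ** 2)
    unit = sp_signal.lfilter([1.0], [1.0, -rho], e)
    # first pass: place beats with the global mean spacing to look up the
    # slowly varying target mean and SD, then respace
    t0_s = np.cumsum(np.full(n_beats, mean_ibi.mean() / 1000.0))
    grid_s = (t_h - t_h[0]) * 3600.0
    mu_i = np.interp(t0_s, grid_s, mean_ibi)
    sd_i = np.interp(t0_s, grid_s, sd_t)
    ibis = np.maximum(mu_i + unit * sd_i, 300.0)
    # measurement artifacts: rare missed beats double an interval
    art = rng.random(n_beats) < 5e-4
    t_s = np.cumsum(ibis) / 1000.0
    ibis = np.where(art, ibis * 2.0, ibis)
    keep = t_s <= n_days * 86400.0
    ibi = pd.Series(ibis[keep],
                    index=start + pd.to_timedelta(t_s[keep], unit="s"),
                    name="ibi_ms")

    # -- steps ----------------------------------------------------------------
    step_edges = pd.date_range(start, end, freq="10min", inclusive="left")
    s0 = step_edges.asi8 / 3.6e12
    s1 = s0 + 10.0 / 60.0
    asleep_at = np.interp(s0, t_h, asleep.astype(float)) > 0.5
    bout_at = np.interp((s0 + s1) / 2.0 - h0 + h0, t_h, bout_level)
    lam = np.where(asleep_at, 0.0, 30.0) + 900.0 * bout_at
    counts = rng.poisson(lam)
    steps = pd.DataFrame({"start": step_edges,
                          "end": step_edges + pd.Timedelta(minutes=10),
                          "steps": counts})

    bundle = SensorBundle(
        participant_id=pid,
        hr=pd.Series(hr, index=index, name="value"),
        eda=pd.Series(eda, index=index, name="value"),
        temp=pd.Series(temp, index=index, name="value"),
        acc=pd.Series(acc, index=index, name="value"),
        ibi=ibi, steps=steps)
    return _Streams(bundle=bundle, schedule=schedule, bouts=bouts)


def generate_weather(days: int, seed) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    tz = timezone(timedelta(hours=1))
    start = pd.Timestamp(_START, tz=tz).normalize()
    rows = []
    phase = rng.uniform(0, 2 * np.pi)
    for d in range(days + 2):
        temp_mean = 12.0 + 6.0 * np.sin(2 * np.pi * d / 28.0 + phase) \
            + rng.normal(0, 2.5)
        temp_min = temp_mean - (3.0 + abs(rng.normal(1.5, 1.0)))
        rows.append({
            "date": (start + pd.Timedelta(days=d)).date(),
            "temp_mean": round(temp_mean, 2),
            "temp_min": round(temp_min, 2),
            "temp_felt_min": round(temp_min - abs(rng.normal(0.8, 0.8)), 2),
            "dew_mean": round(temp_mean - (5.0 + abs(rng.normal(2.0, 1.0))), 2),
            "humidity_mean": round(float(np.clip(rng.normal(70, 12), 30, 100)), 1),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ratings from truth
# ---------------------------------------------------------------------------

def generate_ratings(features_norm: FeatureTable, truth: TruthModel,
                     seed, participants: pd.DataFrame) -> pd.DataFrame:
    """Latent additive model over normalized features -> VAS on 1..10.

    latent = sum_j g_j(x_j) + N(0, noise_sd^2);
    VAS = clip(participant_mean + participant_sd * latent, 1, 10), rounded
    to 0.1.  Missing truth features contribute zero (with a warning); at the
    study conditions they do not occur because ratings are generated from
    the pre-missingness table.
    """
    available = set(features_norm.feature_names)
    bad = [e.feature for effs in truth.effects.values() for e in effs
           if e.feature not in available]
    if bad:
        raise ParameterError(
            f"truth references features absent from the table: "
            f"{sorted(set(bad))}")
    rng = np.random.default_rng(seed)
    meta = participants.set_index("id")
    df = features_norm.df
    mask = features_norm.mask
    out = []
    for pid, idx in df.groupby("participant_id").groups.items():
        group = str(meta.loc[pid, "group"])
        effects = truth.effects.get(group, [])
        latent = rng.normal(0.0, truth.noise_sd, size=len(idx))
        for e in effects:
            x = df.loc[idx, e.feature].to_numpy(dtype=float)
            ok = mask.loc[idx, e.feature].to_numpy()
            if not ok.all():
                warnings.warn(f"truth feature {e.feature} missing for "
                              f"{(~ok).sum()} ratings of {pid}; zero filled")
            latent += np.where(ok, e(np.nan_to_num(x)), 0.0)
        vas = np.clip(meta.loc[pid, "mean_vas"]
                      + meta.loc[pid, "sd_vas"] * latent, 1.0, 10.0)
        vas = np.round(vas, 1)
        sub = df.loc[idx, ["rating_id", "participant_id", "rating_time"]].copy()
        sub["vas"] = vas
        sub["latent"] = latent
        out.append(sub)
    if not out:
        return pd.DataFrame(columns=["rating_id", "participant_id",
                                     "rating_time", "vas", "latent"])
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# missingness injection
# ---------------------------------------------------------------------------

def inject_missingness(bundle: SensorBundle, rating_times, rate: float,
                       seed, config: RunConfig | None = None
                       ) -> tuple[SensorBundle, list[int]]:
    """Corrupt the hour before ``round(rate * n)`` ratings.

    85% of corrupted ratings get a motion burst (the arm moves throughout
    the pre-rating hour, so no 5-min rest window survives and the 1-h
    cardiac features go missing — the dominant real-world mechanism); the
    rest get an EDA dropout (sensor-swap style gap).  Returns the corrupted
    bundle and the indices of the chosen ratings.
    """
    config = config or RunConfig()
    if not 0 <= rate < 1:
        raise ParameterError("rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    times = list(rating_times)
    n_hit = int(round(rate * len(times)))
    if n_hit == 0:
        return bundle, []
    # prefer ratings whose pre-rating hour contains no other rating, so a
    # burst rarely spills into a neighbour's window and the realized
    # incomplete fraction tracks the requested rate
    isolated, crowded = [], []
    for i, t in enumerate(times):
        others = [u for j, u in enumerate(times) if j != i
                  and t - pd.Timedelta(minutes=70) <= u < t]
        (crowded if others else isolated).append(i)
    pool = (rng.permutation(np.array(isolated, dtype=int)).tolist()
            + rng.permutation(np.array(crowded, dtype=int)).tolist())
    chosen = sorted(pool[:n_hit])
    acc = bundle.acc.copy()
    eda = bundle.eda.copy()
    hit_window = pd.Timedelta(minutes=70)
    for i in chosen:
        t = times[i]
        sel = (acc.index >= t - hit_window) & (acc.index < t)
        if rng.random() < 0.85:
            burst = 0.5 + np.abs(rng.normal(0.4, 0.35, int(sel.sum())))
            acc.iloc[np.nonzero(sel)[0]] = burst
        else:
            eda.iloc[np.nonzero(sel)[0]] = np.nan
    out = SensorBundle(participant_id=bundle.participant_id, hr=bundle.hr,
                       eda=eda, temp=bundle.temp, acc=acc, ibi=bundle.ibi,
                       steps=bundle.steps)
    return out, chosen


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    spec: CohortSpec
    truth: TruthModel
    participants: pd.DataFrame
    bundles: dict[str, SensorBundle]
    ratings: dict[str, pd.DataFrame]
    schedules_true: dict[str, SleepSchedule]
    weather: pd.DataFrame
    features_clean: FeatureTable
    features_observed: FeatureTable
    ages: dict[str, float] = field(default_factory=dict)

    def all_ratings(self) -> pd.DataFrame:
        return pd.concat(self.ratings.values(), ignore_index=True)


def _make_participants(spec: CohortSpec, rng) -> pd.DataFrame:
    rows = []
    group_base = {Group.CO: (3.8, 33.9), Group.MS_I: (3.6, 34.3),
                  Group.MS_II: (4.5, 39.1)}
    counts = [(Group.CO, spec.n_co, "CO"), (Group.MS_I, spec.n_ms1, "MS1"),
              (Group.MS_II, spec.n_ms2, "MS2")]
    for group, n, tag in counts:
        base_vas, base_age = group_base[group]
        for i in range(n):
            age = float(np.clip(rng.normal(base_age, 9.0), 18.0, 65.0))
            if group is Group.CO:
                compass = float(rng.uniform(0.0, 12.0))
            elif group is Group.MS_I:
                compass = float(rng.uniform(2.0, 17.0))
            else:
                compass = float(rng.uniform(17.5, 45.0))
            mean_vas = float(np.clip(rng.normal(base_vas, 1.0), 1.5, 8.0))
            fsmc = (float(np.clip(8.0 + 10.0 * mean_vas + rng.normal(0, 7.0),
                                  20.0, 100.0))
                    if group is not Group.CO else np.nan)
            rows.append({
                "id": f"{tag}{i + 1:02d}", "group": group.value,
                "age": round(age, 1),
                "sex": (Sex.FEMALE if rng.random() < 0.6 else Sex.MALE).value,
                "compass": round(compass, 1),
                "fsmc": round(fsmc, 1) if np.isfinite(fsmc) else np.nan,
                "mean_vas": round(mean_vas, 2),
                "sd_vas": round(float(np.clip(rng.normal(1.5, 0.3), 0.8, 2.5)), 2),
            })
    return pd.DataFrame(rows)


def _draw_rating_times(schedule: SleepSchedule, spec: CohortSpec, rng,
                       pid: str) -> pd.DataFrame:
    """Per-day Poisson counts, times uniform over [wake + 1h, onset - 5min]."""
    rows = []
    k = 0
    periods = schedule.periods
    for day in range(1, spec.days + 1):
        wake = periods[day - 1].wake
        onset = periods[day].onset if day < len(periods) else \
            wake + pd.Timedelta(hours=16)
        lo = wake + pd.Timedelta(hours=1)
        hi = onset - pd.Timedelta(minutes=5)
        if hi <= lo:
            continue
        for _ in range(rng.poisson(spec.ratings_per_day)):
            t = lo + (hi - lo) * rng.random()
            rows.append({"rating_id": f"{pid}_r{k:03d}",
                         "participant_id": pid,
                         "timestamp": t.floor("min"), "vas": np.nan})
            k += 1
    df = pd.DataFrame(rows, columns=["rating_id", "participant_id",
                                     "timestamp", "vas"])
    return df.sort_values("timestamp", ignore_index=True) if len(df) else df


def generate_cohort(spec: CohortSpec, truth: TruthModel | None = None,
                    config: RunConfig | None = None) -> Cohort:
    """Generate a full synthetic cohort (pure function of spec/truth/seed).

    Streams are simulated, features extracted with the pipeline's own
    extractor (using its estimated sleep schedule), normalized, and fed to
    the ground-truth model to produce VAS ratings; missingness is then
    injected into the streams and features re-extracted to give the
    *observed* table downstream stages would see.
    """
    config = config or RunConfig()
    truth = truth or default_truth(noise_sd=spec.noise_sd)
    truth.validate()
    root = np.random.SeedSequence(spec.seed)
    s_participants, s_weather, s_ratings, s_streams, s_missing = \
        root.spawn(5)
    rng_p = np.random.default_rng(s_participants)
    participants = _make_participants(spec, rng_p)
    weather = generate_weather(spec.days, s_weather)

    stream_seeds = s_streams.spawn(len(participants))
    rating_rngs = [np.random.default_rng(s) for s in
                   s_ratings.spawn(len(participants) + 1)]
    missing_seeds = s_missing.spawn(len(participants))

    bundles, schedules, ratings, ages = {}, {}, {}, {}
    tables_clean = []
    for i, row in enumerate(participants.itertuples(index=False)):
        pid = row.id
        sim = _simulate_participant(pid, row.age, spec, config,
                                    stream_seeds[i])
        bundles[pid] = sim.bundle
        schedules[pid] = sim.schedule
        ages[pid] = row.age
        ratings[pid] = _draw_rating_times(sim.schedule, spec,
                                          rating_rngs[i], pid)
        est_schedule = estimate_sleep_wake(sim.bundle.acc, sim.bundle.hr,
                                           config)
        tables_clean.append(fx.assemble_features(
            sim.bundle, ratings[pid], est_schedule, weather, row.age,
            config, participant_id=pid))
    features_clean = FeatureTable.concat(tables_clean)

    norm_clean, _ = preprocess.normalize_per_participant(features_clean)
    rated = generate_ratings(norm_clean, truth, rating_rngs[-1],
                             participants)
    vas_by_id = rated.set_index("rating_id")["vas"]
    features_clean.df["vas"] = features_clean.df["rating_id"].map(
        vas_by_id).to_numpy()
    for pid in ratings:
        ratings[pid]["vas"] = ratings[pid]["rating_id"].map(
            vas_by_id).to_numpy()

    # inject gaps and re-extract the observed table
    if spec.missing_rate > 0:
        tables_obs = []
        for i, row in enumerate(participants.itertuples(index=False)):
            pid = row.id
            corrupted, _ = inject_missingness(
                bundles[pid], ratings[pid]["timestamp"], spec.missing_rate,
                missing_seeds[i], config)
            bundles[pid] = corrupted
            est_schedule = estimate_sleep_wake(corrupted.acc, corrupted.hr,
                                               config)
            tables_obs.append(fx.assemble_features(
                corrupted, ratings[pid], est_schedule, weather, row.age,
                config, participant_id=pid))
        features_observed = FeatureTable.concat(tables_obs)
    else:
        features_observed = features_clean.copy()

    return Cohort(spec=spec, truth=truth, participants=participants,
                  bundles=bundles, ratings=ratings, schedules_true=schedules,
                  weather=weather, features_clean=features_clean,
                  features_observed=features_observed, ages=ages)
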