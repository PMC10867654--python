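"""On-disk formats and in-memory containers.

Everything is plain CSV + JSON for inspectability.  Timestamps are stored in
local time with an explicit UTC offset (fatigue is diurnal in local time);
missing cells are written as empty strings and tracked by explicit boolean
mask columns so that no stage can silently drop missingness information.

Per-participant sensor layout (one directory per participant)::

    hr.csv, eda.csv, temp.csv, acc.csv   timestamp,value      (uniform series)
    ibi.csv                              timestamp,ibi_ms     (event series)
    steps.csv                            start,end,steps      (interval counts)
    ratings.csv                          rating_id,timestamp,vas
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import FormatError, RunConfig, feature_group

UNIFORM_CHANNELS = ("hr", "eda", "temp", "acc")
MANDATORY_CHANNELS = UNIFORM_CHANNELS + ("ibi", "steps")

META_COLUMNS = ("rating_id", "participant_id", "rating_time", "vas")


# ---------------------------------------------------------------------------
# sensor bundle
# ---------------------------------------------------------------------------

@dataclass
class SensorBundle:
    """One participant's raw channels over the study window.

    ``hr``/``eda``/``temp``/``acc`` are uniform series (NaN marks a gap, the
    sample itself is never dropped); ``ibi`` is an event series indexed by
    beat time with interval values in ms; ``steps`` holds interval counts.
    """

    participant_id: str
    hr: pd.Series
    eda: pd.Series
    temp: pd.Series
    acc: pd.Series
    ibi: pd.Series
    steps: pd.DataFrame

    def channels(self) -> dict[str, pd.Series]:
        return {"hr": self.hr, "eda": self.eda, "temp": self.temp,
                "acc": self.acc}

    def span(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return self.hr.index[0], self.hr.index[-1]


def _check_monotone(ts: pd.Series | pd.DatetimeIndex, path) -> None:
    values = pd.DatetimeIndex(ts).asi8
    bad = np.nonzero(np.diff(values) < 0)[0]
    if bad.size:
        row = int(bad[0]) + 2  # +1 for 0-base, +1 for the regression row
        raise FormatError(f"{path}: timestamp regression at row {row}")


def _read_series(path: Path, value_col: str = "value") -> pd.Series:
    df = pd.read_csv(path, float_precision="round_trip")
    expected = {"timestamp", value_col}
    if not expected.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(expected)}")
    idx = pd.to_datetime(df["timestamp"], format="ISO8601")
    _check_monotone(idx, path)
    return pd.Series(df[value_col].to_numpy(dtype=float), index=idx,
                     name=value_col)


def _write_series(series: pd.Series, path: Path,
                  value_col: str = "value") -> None:
    out = pd.DataFrame({
        "timestamp": [t.isoformat() for t in series.index],
        value_col: series.to_numpy(),
    })
    out.to_csv(path, index=False, float_format="%.17g")


def load_sensor_bundle(directory) -> SensorBundle:
    """Load one participant's channel CSVs.

    Raises :class:`FormatError` naming the channel if a mandatory file is
    missing, or citing the offending row on a timestamp regression.
    """
    directory = Path(directory)
    for channel in MANDATORY_CHANNELS:
        name = f"{channel}.csv"
        if not (directory / name).exists():
            raise FormatError(f"channel {channel} missing in {directory}")
    series = {ch: _read_series(directory / f"{ch}.csv")
              for ch in UNIFORM_CHANNELS}
    ibi = _read_series(directory / "ibi.csv", value_col="ibi_ms")
    steps = pd.read_csv(directory / "steps.csv")
    if not {"start", "end", "steps"}.issubset(steps.columns):
        raise FormatError(f"{directory / 'steps.csv'}: expected start,end,steps")
    steps["start"] = pd.to_datetime(steps["start"], format="ISO8601")
    steps["end"] = pd.to_datetime(steps["end"], format="ISO8601")
    _check_monotone(steps["start"], directory / "steps.csv")
    return SensorBundle(participant_id=directory.name, ibi=ibi, steps=steps,
                        **series)


def write_sensor_bundle(bundle: SensorBundle, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for ch, series in bundle.channels().items():
        _write_series(series, directory / f"{ch}.csv")
    _write_series(bundle.ibi, directory / "ibi.csv", value_col="ibi_ms")
    out = bundle.steps.copy()
    out["start"] = [t.isoformat() for t in out["start"]]
    out["end"] = [t.isoformat() for t in out["end"]]
    out.to_csv(directory / "steps.csv", index=False)


def read_ratings(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"rating_id", "timestamp", "vas"}.issubset(df.columns):
        raise FormatError(f"{path}: expected rating_id,timestamp,vas")
    df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    _check_monotone(df["timestamp"], path)
    return df


def write_ratings(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["timestamp"] = [t.isoformat() for t in out["timestamp"]]
    out.to_csv(path, index=False)


def read_weather(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "date" not in df.columns:
        raise FormatError(f"{path}: expected a 'date' column")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def write_weather(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_participants(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"id", "group", "age", "sex", "compass"}
    if not needed.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(needed)}")
    return df


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """The modeling matrix: one row per fatigue rating.

    ``df`` holds the meta columns (rating_id, participant_id, rating_time,
    vas, and after preprocessing vas_norm) plus one float column per feature
    where NaN marks a missing value before imputation.  ``mask`` is aligned
    boolean (True = observed).  ``groups`` tags every feature with its
    feature group (CAR/EDA/ACC/WEA/ROUTINE).
    """

    df: pd.DataFrame
    mask: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for f in self.feature_names:
            if f not in self.mask.columns:
                raise FormatError(f"mask column missing for feature {f!r}")
        if not self.groups:
            self.groups = {f: feature_group(f) for f in self.feature_names}

    @property
    def feature_names(self) -> list[str]:
        meta = set(META_COLUMNS) | {"vas_norm", "group"}
        return [c for c in self.df.columns if c not in meta]

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.df.copy(), self.mask.copy(),
                            dict(self.groups))

    def participants(self) -> list[str]:
        return list(pd.unique(self.df["participant_id"]))

    def incomplete_rows(self) -> np.ndarray:
        """Boolean: rows with at least one missing feature."""
        names = self.feature_names
        if not names:
            return np.zeros(len(self.df), dtype=bool)
        return (~self.mask[names].to_numpy(dtype=bool)).any(axis=1)

    def features_in_groups(self, tags) -> list[str]:
        tags = set(tags)
        return [f for f in self.feature_names if self.groups[f] in tags]

    @classmethod
    def concat(cls, tables) -> "FeatureTable":
        tables = list(tables)
        df = pd.concat([t.df for t in tables], ignore_index=True)
        mask = pd.concat([t.mask for t in tables], ignore_index=True)
        groups = dict(tables[0].groups)
        return cls(df, mask, groups)


def write_feature_table(table: FeatureTable, path) -> None:
    """CSV with one ``<feature>__mask`` boolean column per feature; missing
    cells are written as empty strings."""
    out = table.df.copy()
    if "rating_time" in out.columns:
        out["rating_time"] = [t.isoformat() for t in out["rating_time"]]
    for f in table.feature_names:
        out[f"{f}__mask"] = table.mask[f].to_numpy()
    out.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path, config: RunConfig | None = None) -> FeatureTable:
    raw = pd.read_csv(path, float_precision="round_trip")
    mask_cols = [c for c in raw.columns if c.endswith("__mask")]
    feature_cols = [c[:-6] for c in mask_cols]
    for mc, fc in zip(mask_cols, feature_cols):
        if fc not in raw.columns:
            raise FormatError(
                f"{path}: mask column {mc!r} without feature column {fc!r}")
    mask = raw[mask_cols].astype(bool)
    mask.columns = feature_cols
    df = raw.drop(columns=mask_cols)
    if "rating_time" in df.columns:
        df["rating_time"] = pd.to_datetime(df["rating_time"],
                                           format="ISO8601")
    for fc in feature_cols:
        df[fc] = pd.to_numeric(df[fc])
        bad = df[fc].isna() & mask[fc].to_numpy()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0]) + 2
            raise FormatError(
                f"{path}: cell missing for {fc!r} at row {row} but mask "
                f"says present")
    overrides = config.feature_groups if config else None
    groups = {f: feature_group(f, overrides) for f in feature_cols}
    return FeatureTable(df, mask, groups)


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def write_manifest(path, stage: str, config: RunConfig, **counts) -> None:
    """Stage manifest: seed, config hash and row counts.  Deliberately free
    of wall-clock fields so identical runs are byte-identical."""
    payload = {"stage": stage, "seed": config.seed,
               "config_hash": config.hash(), "counts": counts}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
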