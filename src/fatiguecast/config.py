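"""Run configuration, participant metadata and shared error types.

All tunable thresholds of the pipeline live in :class:`RunConfig` so that a
single YAML file reproduces a run end to end.  Defaults follow the study
protocol where the protocol states a value (rest threshold 0.55 of maximum
heart rate, elimination thresholds 0.1 EDF / 0.05 p, 1000 subsamples) and are
the package's own documented choices otherwise.
"""

from __future__ import annotations

import dataclasses
import enum
import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping

import yaml


class FatiguecastError(Exception):
    """Base class for all package errors."""


class FormatError(FatiguecastError):
    """Malformed on-disk data (bad schema, non-monotone timestamps, ...)."""


class DependencyError(FatiguecastError):
    """A pipeline stage was requested before its inputs exist."""


class InsufficientDataError(FatiguecastError):
    """Not enough data to run an operation (e.g. < 24 h for sleep detection)."""


class ParameterError(FatiguecastError):
    """Infeasible or invalid parameter combination."""


class Group(str, enum.Enum):
    """Participant subgroup: healthy controls, MS with functional ANS (MS I,
    abbreviated autonomic-symptom score <= 17) and MS with dysfunctional ANS
    (MS II, score > 17)."""

    CO = "CO"
    MS_I = "MS_I"
    MS_II = "MS_II"


class Sex(str, enum.Enum):
    FEMALE = "F"
    MALE = "M"


# The five aggregation horizons anchored to each fatigue rating.
HORIZONS = ("1h", "3h", "6h", "aw", "as")

FEATURE_GROUPS = ("CAR", "EDA", "ACC", "WEA", "ROUTINE")

ROUTINE_FEATURES = ("time_of_day", "time_awake", "sleep_duration",
                    "wake_dev", "bed_dev")


@dataclass(frozen=True)
class Participant:
    """Study participant metadata.

    ``group`` is MS_II iff the participant is an MS patient whose abbreviated
    COMPASS score exceeds 17, MS_I for MS patients at or below 17, CO for
    healthy controls.  ``fsmc`` (trait-fatigue questionnaire total) may be
    absent (None), as for most controls in the study.
    """

    id: str
    group: Group
    age: float
    sex: Sex
    compass: float
    fsmc: float | None = None

    def __post_init__(self) -> None:
        if not 18 <= self.age <= 65:
            raise ParameterError(f"age {self.age} outside [18, 65]")
        if self.compass < 0:
            raise ParameterError("compass score must be >= 0")
        if self.group is Group.MS_II and self.compass <= 17:
            raise ParameterError("MS_II requires compass > 17")
        if self.group is Group.MS_I and self.compass > 17:
            raise ParameterError("MS_I requires compass <= 17")


def classify_ms_group(compass: float) -> Group:
    """ANS-dysfunction rule for MS patients: score > 17 -> MS_II else MS_I."""
    return Group.MS_II if compass > 17 else Group.MS_I


@dataclass
class RunConfig:
    """All pipeline parameters.

    Parameters
    ----------
    seed
        Master seed; every stochastic stage derives its RNG from it.
    sampling_rate_hz
        Sampling rate of the uniform channels (HR, EDA, skin temperature,
        acceleration).  1 Hz is the device rate; 1/60 Hz keeps synthetic
        suites fast and is the default here.
    n_subsamples
        Subsamples per backward-elimination iteration (each excludes two
        participants).
    edf_threshold, p_threshold
        Elimination rules: purge terms whose mean EDF falls below
        ``edf_threshold``; then drop the worst term with mean p above
        ``p_threshold``.
    rest_hr_fraction
        A 5-min window counts as rest only if its mean HR is below this
        fraction of the age-predicted maximum (220 - age).
    motion_sd_threshold
        "No measurable continuous arm motion": population SD of acceleration
        magnitude within the 5-min window must stay below this (generator
        units).
    """

    seed: int = 0
    sampling_rate_hz: float = 1.0 / 60.0
    n_subsamples: int = 1000
    n_perturbations: int = 100
    edf_threshold: float = 0.1
    p_threshold: float = 0.05
    rest_hr_fraction: float = 0.55
    horizon_hours: tuple[int, ...] = (1, 3, 6)
    motion_sd_threshold: float = 0.05
    rest_window_minutes: int = 5
    artifact_dev_fraction: float = 0.25
    max_interpolated_ibis: int = 3
    min_window_ibis: int = 10
    eda_highpass_hz: float = 0.05
    eda_prominence: float = 0.05
    basis_dim: int = 10
    smooth_criterion: str = "efs"          # "efs" (REML-like) or "gcv"
    optimizer_restarts: int = 3
    optimizer_maxiter: int = 40
    sleep_acc_quantiles: tuple[float, float] = (0.2, 0.8)
    sleep_min_minutes: int = 180
    sleep_gap_minutes: int = 20
    utc_offset_hours: int = 1
    feature_groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = {
            "sampling_rate_hz": self.sampling_rate_hz,
            "n_subsamples": self.n_subsamples,
            "edf_threshold": self.edf_threshold,
            "rest_hr_fraction": self.rest_hr_fraction,
            "motion_sd_threshold": self.motion_sd_threshold,
            "eda_prominence": self.eda_prominence,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ParameterError(f"{name} must be strictly positive")
        if not 0 < self.p_threshold < 1:
            raise ParameterError("p_threshold must lie in (0, 1)")
        if self.basis_dim < 4:
            raise ParameterError("basis_dim must be >= 4 (cubic splines)")
        if self.smooth_criterion not in ("gcv", "efs"):
            raise ParameterError("smooth_criterion must be 'gcv' or 'efs'")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["horizon_hours"] = list(self.horizon_hours)
        d["sleep_acc_quantiles"] = list(self.sleep_acc_quantiles)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "horizon_hours" in d:
            d["horizon_hours"] = tuple(d["horizon_hours"])
        if "sleep_acc_quantiles" in d:
            d["sleep_acc_quantiles"] = tuple(d["sleep_acc_quantiles"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def feature_group(name: str, overrides: Mapping[str, str] | None = None) -> str:
    """Map a feature name to its group tag (CAR/EDA/ACC/WEA/ROUTINE).

    Cardiac: HR and the Poincaré HRV metrics.  Electrodermal: EDA level and
    peak features, plus skin temperature (same skin-surface modality; no
    dedicated group exists for it).  Physical activity: acceleration and step
    features.  Weather: day-level weather.  Routine: time-of-day and
    sleep-schedule features.
    """
    if overrides and name in overrides:
        return overrides[name]
    if name in ROUTINE_FEATURES:
        return "ROUTINE"
    prefix = name.split("_", 1)[0]
    if prefix in ("hr", "sdnn", "sd1", "sd2"):
        return "CAR"
    if prefix in ("eda", "edapeaks", "skintemp"):
        return "EDA"
    if prefix in ("act", "steps"):
        return "ACC"
    if prefix == "wea":
        return "WEA"
    raise KeyError(f"cannot infer feature group for {name!r}")
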