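"""Per-participant normalization, zero-imputation and complete-case split.

Every feature column and the VAS rating are z-scored within each participant
over the full study (mean subtracted, divided by the population SD, both
computed ignoring missing values).  After normalization, zero equals the
participant's mean, so missing values are imputed with zero.  Models are
trained on complete cases (rows with no imputed cell) and can be evaluated
with or without the imputed rows.

The population (divide-by-n) SD convention makes small hand examples exact;
normalization statistics are computed once per participant over the whole
study, not per cross-validation fold, mirroring the modeled protocol (the
mild train/test leakage this implies is discussed in the methods note).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import FatiguecastError
from .io import FeatureTable


class NormalizationStats:
    """Per participant x column means and population SDs.

    ``frame`` is long-form with columns participant_id, column, mean, sd,
    n_obs.  Columns with fewer than 2 observed values or zero variance for a
    participant get sd = NaN and are masked in the normalized table.
    """

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame
        self._lookup = {(r.participant_id, r.column): (r.mean, r.sd)
                        for r in frame.itertuples(index=False)}

    def get(self, participant_id: str, column: str) -> tuple[float, float]:
        return self._lookup[(participant_id, column)]

    def denormalize(self, participant_id: str, column: str,
                    values) -> np.ndarray:
        mean, sd = self.get(participant_id, column)
        return np.asarray(values, dtype=float) * sd + mean


def normalize_per_participant(
        table: FeatureTable,
        min_obs: int = 2) -> tuple[FeatureTable, NormalizationStats]:
    """Z-score features and VAS within each participant (population SD).

    Zero-variance or under-observed columns are masked for that participant
    with a warning rather than divided by zero.  The VAS rating is normalized
    identically into a ``vas_norm`` column (raw ``vas`` is kept).
    """
    out = table.copy()
    records = []
    columns = table.feature_names + ["vas"]
    for pid, idx in out.df.groupby("participant_id").groups.items():
        for col in columns:
            values = out.df.loc[idx, col].to_numpy(dtype=float)
            obs = np.isfinite(values)
            n_obs = int(obs.sum())
            mean = float(np.mean(values[obs])) if n_obs else np.nan
            sd = float(np.std(values[obs])) if n_obs else np.nan
            usable = n_obs >= min_obs and sd > 0
            records.append({"participant_id": pid, "column": col,
                            "mean": mean, "sd": sd if usable else np.nan,
                            "n_obs": n_obs})
            target = "vas_norm" if col == "vas" else col
            if usable:
                normed = (values - mean) / sd
            else:
                if n_obs:
                    warnings.warn(
                        f"column {col!r} for participant {pid}: "
                        f"{'zero variance' if n_obs >= min_obs else 'too few values'};"
                        " masked")
                normed = np.full_like(values, np.nan)
            if target == "vas_norm":
                out.df.loc[idx, "vas_norm"] = normed
            else:
                out.df.loc[idx, col] = normed
                out.mask.loc[idx, col] = np.isfinite(normed)
    stats = NormalizationStats(pd.DataFrame.from_records(records))
    return out, stats


def impute_zero(table: FeatureTable) -> tuple[FeatureTable, pd.DataFrame]:
    """Replace every missing normalized cell with zero (the participant
    mean).  Returns the completed table and the imputation mask (True where
    a cell was imputed); observed cells are never altered."""
    out = table.copy()
    names = out.feature_names
    imputed = ~out.mask[names].copy()
    values = out.df[names].to_numpy(dtype=float)
    values[imputed.to_numpy()] = 0.0
    out.df[names] = values
    return out, imputed


def complete_cases(table: FeatureTable,
                   imputed: pd.DataFrame | None = None) -> FeatureTable:
    """Rows with no imputed/missing cell (training set of the protocol)."""
    if imputed is not None:
        drop = imputed.to_numpy().any(axis=1)
    else:
        drop = table.incomplete_rows()
    keep = ~drop
    out = table.copy()
    out.df = out.df.loc[keep].reset_index(drop=True)
    out.mask = out.mask.loc[keep].reset_index(drop=True)
    return out


def require_rows(table: FeatureTable, minimum: int, context: str) -> None:
    if len(table) < minimum:
        raise FatiguecastError(
            f"{context}: only {len(table)} rows available (< {minimum})")
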