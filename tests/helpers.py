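"""Shared builders for feature-level synthetic tables (no sensor streams).

These tables mimic the post-normalization modeling matrix directly:
participant-structured standard-normal features and a response assembled
from known effects plus noise.  They exercise the modeling and evaluation
layers without paying for stream simulation.
"""

import numpy as np
import pandas as pd

from fatiguecast.io import FeatureTable


def feature_table(n_participants: int, ratings_per: int, effects: dict,
                  noise_sd: float, seed, n_noise_features: int = 0,
                  missing_rate: float = 0.0,
                  missing_features: list | None = None) -> FeatureTable:
    """Build a normalized feature table with known ground truth.

    ``effects`` maps feature name -> callable on the standard-normal
    feature; ``n_noise_features`` adds unrelated columns f_noise_*;
    ``missing_rate`` masks cells of ``missing_features`` (default: the
    effect features) at random, leaving the response untouched.
    """
    rng = np.random.default_rng(seed)
    n = n_participants * ratings_per
    pids = np.repeat([f"P{i:02d}" for i in range(n_participants)],
                     ratings_per)
    cols = {}
    y = rng.normal(0.0, noise_sd, n)
    for name, g in effects.items():
        x = rng.normal(0.0, 1.0, n)
        cols[name] = x
        y = y + g(x)
    for j in range(n_noise_features):
        cols[f"f_noise_{j}"] = rng.normal(0.0, 1.0, n)
    data = pd.DataFrame(cols)
    mask = data.notna()
    if missing_rate > 0:
        targets = missing_features or list(effects)
        for name in targets:
            hit = rng.random(n) < missing_rate
            data.loc[hit, name] = np.nan
            mask.loc[hit, name] = False
    df = pd.concat([
        pd.DataFrame({
            "rating_id": [f"r{i}" for i in range(n)],
            "participant_id": pids,
            "rating_time": pd.Timestamp("2021-03-01 12:00",
                                        tz="UTC").tz_convert(None),
            "vas": 5.0, "vas_norm": y}),
        data], axis=1)
    groups = {c: "CAR" for c in data.columns}
    return FeatureTable(df, mask, groups)


def impute_zeros_inplace(table: FeatureTable) -> FeatureTable:
    """Zero-fill masked cells (the tables above are already normalized)."""
    out = table.copy()
    names = out.feature_names
    vals = out.df[names].to_numpy(dtype=float)
    vals[~out.mask[names].to_numpy()] = 0.0
    out.df[names] = vals
    return out
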