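"""Within-group (leave-one-participant-out) and across-group evaluation.

Explained variance is defined about zero: after per-participant
normalization, zero IS the participant's mean rating, so

    R2 = 1 - sum (y - yhat)^2 / sum y^2        (reported in percent)

which makes the per-participant-mean baseline regressor (predict 0) score
exactly R2 = 0 for every participant and any data — the reference point all
models are compared against.  Group metrics are unweighted means over the
test group's participants.  Models are always trained on complete cases;
each test participant is scored twice, on their complete cases only and on
all their rows with zero-imputed gaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import FatiguecastError, RunConfig
from .gam import GamDesign
from .io import FeatureTable
from .selection import backward_eliminate

_METRICS = ("r2", "mae", "rmse")


def participant_metrics(y, yhat) -> dict:
    """R2 (percent, about zero), MAE and RMSE for one participant."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size == 0:
        raise FatiguecastError("participant_metrics: empty input")
    resid = y - yhat
    sse = float(resid @ resid)
    sst = float(y @ y)
    r2 = 100.0 * (1.0 - sse / sst) if sst > 0 else 0.0
    return {"r2": r2,
            "mae": float(np.mean(np.abs(resid))),
            "rmse": float(np.sqrt(np.mean(resid ** 2)))}


@dataclass
class EvalResult:
    """Per-participant and group-mean metrics for one train/test pairing.

    ``per_participant`` columns: participant_id, n_cc, n_all, then r2/mae/
    rmse with ``_cc`` (complete cases only) and ``_imp`` (all rows, imputed)
    suffixes.  Group means are unweighted across participants.
    """

    train_group: str
    test_group: str
    per_participant: pd.DataFrame
    n_rows_cc: int
    n_rows_all: int

    @property
    def n_participants(self) -> int:
        return len(self.per_participant)

    def group_mean(self, metric: str = "r2", variant: str = "cc") -> float:
        col = f"{metric}_{variant}"
        return float(self.per_participant[col].mean())

    def metric_values(self, metric: str = "r2",
                      variant: str = "cc") -> np.ndarray:
        return self.per_participant[f"{metric}_{variant}"].to_numpy()


def _complete_rows(table: FeatureTable) -> np.ndarray:
    return ~table.incomplete_rows()


def _score_participants(table: FeatureTable, pids, predict) -> pd.DataFrame:
    """Score each listed participant with ``predict(rows_df) -> yhat``."""
    complete = _complete_rows(table)
    records = []
    for pid in pids:
        sel = (table.df["participant_id"] == pid).to_numpy()
        rows_cc = sel & complete
        if not sel.any():
            warnings.warn(f"participant {pid}: no test rows; skipped")
            continue
        rec = {"participant_id": pid, "n_cc": int(rows_cc.sum()),
               "n_all": int(sel.sum())}
        for variant, rows in (("cc", rows_cc), ("imp", sel)):
            if rows.any():
                y = table.df.loc[rows, "vas_norm"].to_numpy(dtype=float)
                m = participant_metrics(y, predict(table.df.loc[rows]))
            else:
                m = {k: np.nan for k in _METRICS}
            rec.update({f"{k}_{variant}": v for k, v in m.items()})
        records.append(rec)
    return pd.DataFrame.from_records(records)


def baseline_evaluate(table: FeatureTable,
                      group: str = "baseline") -> EvalResult:
    """The per-participant-mean regressor: predict the normalized mean (0)
    everywhere.  R2 is exactly 0 for every participant by construction."""
    pids = table.participants()
    per = _score_participants(table, pids,
                              lambda rows: np.zeros(len(rows)))
    complete = _complete_rows(table)
    return EvalResult(group, group, per, int(complete.sum()), len(table))


def lopo_evaluate(table: FeatureTable, terms: list[str],
                  config: RunConfig | None = None,
                  group: str = "") -> EvalResult:
    """Leave-one-participant-out: for each participant, fit the group model
    (fixed term set) on the complete cases of everyone else, then score the
    held-out participant."""
    config = config or RunConfig()
    pids = table.participants()
    if len(pids) < 3:
        raise FatiguecastError("LOPO needs >= 3 participants")
    complete = _complete_rows(table)
    y = table.df["vas_norm"].to_numpy(dtype=float)
    design = GamDesign(table.df[terms], y, terms, config) if terms else None
    lam_ref = design.fit(rows=complete).lambdas if design is not None else None
    records = []
    for pid in pids:
        held = (table.df["participant_id"] == pid).to_numpy()
        train = complete & ~held
        if design is not None:
            fit = design.fit(rows=train, lam0=lam_ref)
            predict = fit.predict
        else:
            mu = float(y[train].mean()) if train.any() else 0.0
            predict = lambda rows, mu=mu: np.full(len(rows), mu)
        records.append(_score_participants(
            _subset(table, held), [pid], predict))
    per = pd.concat(records, ignore_index=True) if records else pd.DataFrame()
    return EvalResult(group, group, per, int(complete.sum()), len(table))


def across_group_evaluate(train_table: FeatureTable,
                          test_table: FeatureTable, terms: list[str],
                          config: RunConfig | None = None,
                          train_group: str = "", test_group: str = ""
                          ) -> EvalResult:
    """Fit once on the training group's complete cases, score each test
    participant separately.  Participant sets must be disjoint."""
    config = config or RunConfig()
    overlap = set(train_table.participants()) & set(test_table.participants())
    if overlap:
        raise FatiguecastError(
            f"train/test participants overlap: {sorted(overlap)}")
    complete = _complete_rows(train_table)
    y = train_table.df["vas_norm"].to_numpy(dtype=float)
    if terms:
        design = GamDesign(train_table.df[terms], y, terms, config)
        fit = design.fit(rows=complete)
        predict = fit.predict
    else:
        mu = float(y[complete].mean()) if complete.any() else 0.0
        predict = lambda rows: np.full(len(rows), mu)
    per = _score_participants(test_table, test_table.participants(), predict)
    test_complete = _complete_rows(test_table)
    return EvalResult(train_group, test_group, per,
                      int(test_complete.sum()), len(test_table))


def _subset(table: FeatureTable, rows: np.ndarray) -> FeatureTable:
    out = table.copy()
    out.df = out.df.loc[rows].reset_index(drop=True)
    out.mask = out.mask.loc[rows].reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# paired comparison
# ---------------------------------------------------------------------------

def compare_wilcoxon(metric_a, metric_b) -> float:
    """Two-sided Wilcoxon signed-rank p for paired per-participant metrics.

    Exact null distribution for n <= 25 pairs (zeros dropped first), normal
    approximation with continuity correction otherwise.  If every difference
    is zero the p-value is 1 by convention.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.size < 5:
        raise FatiguecastError(
            "compare_wilcoxon needs >= 5 paired values of equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    method = "exact" if d.size <= 25 else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                         alternative="two-sided", method=method)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# ablation study
# ---------------------------------------------------------------------------

ABLATION_GROUPS = ("CAR", "EDA", "ACC", "WEA")


@dataclass
class AblationResult:
    """Group-mean R2 per feature-subset configuration plus the paired test
    against the routine-only reference."""

    table: pd.DataFrame
    selected: dict = field(default_factory=dict)
    perturbation_stats: dict = field(default_factory=dict)


def ablation_configurations() -> dict[str, tuple[str, ...]]:
    """The 10 configurations: all groups, minus each, only each (+routine),
    routine only.  Routine features are part of every configuration."""
    configs: dict[str, tuple[str, ...]] = {"all": ABLATION_GROUPS}
    for g in ABLATION_GROUPS:
        configs[f"no_{g}"] = tuple(x for x in ABLATION_GROUPS if x != g)
    for g in ABLATION_GROUPS:
        configs[f"only_{g}"] = (g,)
    configs["routine_only"] = ()
    return configs


def ablation_study(table: FeatureTable, candidates: list[str],
                   config: RunConfig | None = None,
                   seed: int | None = None) -> AblationResult:
    """Re-select and re-evaluate the model under feature-group ablations.

    For each configuration, candidates outside the allowed groups are
    dropped (routine candidates always stay), the elimination loop is re-run
    and LOPO gives the configuration's group-mean R2.  Significance against
    the routine-only configuration comes from a paired Wilcoxon test across
    participant perturbations: each perturbation excludes two random
    participants, fits on the remaining complete cases and scores the
    excluded pair (mean R2 over the two); the same exclusion pairs are used
    in every configuration.
    """
    config = config or RunConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    groups = table.groups
    routine = [c for c in candidates if groups[c] == "ROUTINE"]
    pids = np.array(sorted(table.participants()))
    pairs = [rng.choice(pids, size=2, replace=False)
             for _ in range(config.n_perturbations)]

    selected_map: dict[str, list[str]] = {}
    stats_map: dict[str, np.ndarray] = {}
    rows = []
    complete = _complete_rows(table)
    cc_table = _subset(table, complete)
    for name, allowed in ablation_configurations().items():
        cand = routine + [c for c in candidates
                          if groups[c] in allowed and groups[c] != "ROUTINE"]
        if name.startswith("only_") and len(cand) == len(routine):
            warnings.warn(f"ablation config {name}: no candidate features in "
                          "that group; skipped")
            continue
        selected, _ = backward_eliminate(
            cc_table, cand, config,
            seed=int(rng.integers(2 ** 31 - 1)))
        selected_map[name] = selected
        lopo = lopo_evaluate(table, selected, config, group=name)
        stat = _perturbation_stats(table, selected, pairs, config)
        stats_map[name] = stat
        rows.append({"config": name, "n_selected": len(selected),
                     "mean_r2_cc": lopo.group_mean("r2", "cc"),
                     "mean_r2_imp": lopo.group_mean("r2", "imp")})

    out = pd.DataFrame(rows)
    ref = stats_map.get("routine_only")
    p_col = []
    for name in out["config"]:
        if ref is None or name == "routine_only":
            p_col.append(np.nan)
            continue
        s = stats_map[name]
        ok = np.isfinite(s) & np.isfinite(ref)
        p_col.append(compare_wilcoxon(s[ok], ref[ok])
                     if ok.sum() >= 5 else np.nan)
    out["p_vs_routine"] = p_col
    return AblationResult(out, selected_map, stats_map)


def _perturbation_stats(table, terms, pairs, config) -> np.ndarray:
    complete = _complete_rows(table)
    y = table.df["vas_norm"].to_numpy(dtype=float)
    pids_col = table.df["participant_id"].to_numpy()
    design = GamDesign(table.df[terms], y, terms, config) if terms else None
    lam_ref = design.fit(rows=complete).lambdas if design is not None else None
    out = np.full(len(pairs), np.nan)
    for k, pair in enumerate(pairs):
        held = np.isin(pids_col, pair)
        train = complete & ~held
        if design is not None:
            fit = design.fit(rows=train, lam0=lam_ref)
            predict = fit.predict
        else:
            mu = float(y[train].mean()) if train.any() else 0.0
            predict = lambda rows, mu=mu: np.full(len(rows), mu)
        r2s = []
        for pid in pair:
            rows = held & complete & (pids_col == pid)
            if rows.any():
                m = participant_metrics(
                    y[rows], predict(table.df.loc[rows]))
                r2s.append(m["r2"])
        if r2s:
            out[k] = float(np.mean(r2s))
    return out


# ---------------------------------------------------------------------------
# descriptive correlation
# ---------------------------------------------------------------------------

def correlate_mean_vas_fsmc(participants: pd.DataFrame) -> dict:
    """Spearman correlation (mid-rank ties, t-approximation p) between each
    participant's mean raw VAS rating and their trait-fatigue (FSMC) score.

    ``participants`` needs columns ``mean_vas`` and ``fsmc``; rows with a
    missing score are dropped."""
    sub = participants[["mean_vas", "fsmc"]].dropna()
    if len(sub) < 3:
        raise FatiguecastError(
            "correlation needs >= 3 participants with both scores")
    rho, p = stats.spearmanr(sub["mean_vas"], sub["fsmc"])
    return {"rho": float(rho), "p": float(p), "n": int(len(sub))}
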