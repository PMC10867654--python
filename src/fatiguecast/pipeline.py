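"""Stage orchestration: simulate -> extract -> preprocess -> fit ->
evaluate -> ablate, each re-runnable from the previous stage's artifacts.

Every stage writes plain CSV/JSON plus a manifest (seed, config hash, row
counts).  Stages never read anything a previous stage did not write, so a
working directory is a complete, inspectable record of a run.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, io, preprocess, selection, synthetic
from .config import DependencyError, Group, ParameterError, RunConfig
from .features import assemble_features, feature_names
from .gam import GamDesign, classify_shape, partial_effect
from .sleep import estimate_sleep_wake

log = logging.getLogger("fatiguecast")

STAGES = ("simulate", "extract", "preprocess", "fit", "evaluate", "ablate")

GROUP_FILTERS = {
    "all": (Group.CO.value, Group.MS_I.value, Group.MS_II.value),
    "co": (Group.CO.value,),
    "ms": (Group.MS_I.value, Group.MS_II.value),
    "ms1": (Group.MS_I.value,),
    "ms2": (Group.MS_II.value,),
}

# decoy biosignal features with no effect in any default ground truth; a
# curated pool (group truth features + routine + decoys) keeps the selection
# loop at a couple dozen candidates — the full ~200-feature census is
# available by passing candidates explicitly
DECOY_CANDIDATES = [
    "hr_1h_mean", "sdnn_3h_mean", "sd1_6h_sd", "sd2_6h_slope",
    "eda_1h_mean", "eda_aw_sd", "edapeaks_6h_count", "act_3h_sd",
    "skintemp_aw_mean", "wea_temp_min",
]


def default_candidates(table: io.FeatureTable,
                       group: str = "all") -> list[str]:
    """Candidate pool for one group's selection run: routine features, the
    default truth's features for the groups involved, and decoys."""
    truth = synthetic.default_truth()
    members = {"all": list(truth.effects), "co": [Group.CO.value],
               "ms": [Group.MS_I.value, Group.MS_II.value],
               "ms1": [Group.MS_I.value], "ms2": [Group.MS_II.value]}[group]
    routine = [f for f in table.feature_names
               if table.groups[f] == "ROUTINE"]
    pool = list(routine)
    for g in members:
        for e in truth.effects[g]:
            if e.feature not in pool:
                pool.append(e.feature)
    for f in DECOY_CANDIDATES[:6]:
        if f not in pool:
            pool.append(f)
    return pool


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"{path.name} not found — run the '{producer}' stage first")
    return path


def load_config(path) -> tuple[RunConfig, synthetic.CohortSpec]:
    """YAML with optional top-level ``run`` and ``cohort`` sections."""
    import yaml
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    run = RunConfig.from_dict(raw.get("run", {}))
    cohort = synthetic.CohortSpec(**raw.get("cohort", {}))
    return run, cohort


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig, spec: synthetic.CohortSpec,
                   workdir) -> synthetic.Cohort:
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    log.info("simulate: %d participants, %d days",
             spec.n_co + spec.n_ms1 + spec.n_ms2, spec.days)
    cohort = synthetic.generate_cohort(spec, config=config)
    cohort.participants.to_csv(workdir / "participants.csv", index=False)
    io.write_weather(cohort.weather, workdir / "weather.csv")
    with open(workdir / "truth.json", "w") as fh:
        json.dump(cohort.truth.to_record(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    n_ratings = 0
    for pid, bundle in cohort.bundles.items():
        pdir = workdir / pid
        io.write_sensor_bundle(bundle, pdir)
        io.write_ratings(cohort.ratings[pid], pdir / "ratings.csv")
        n_ratings += len(cohort.ratings[pid])
        log.info("simulate: wrote %s (%d ratings)", pid,
                 len(cohort.ratings[pid]))
    io.write_manifest(workdir / "manifest_simulate.json", "simulate", config,
                      participants=len(cohort.participants),
                      ratings=n_ratings, days=spec.days)
    return cohort


def stage_extract(config: RunConfig, workdir) -> io.FeatureTable:
    workdir = Path(workdir)
    participants = io.read_participants(
        _require(workdir / "participants.csv", "simulate"))
    weather = io.read_weather(_require(workdir / "weather.csv", "simulate"))
    tables = []
    for row in participants.itertuples(index=False):
        pdir = _require(workdir / row.id, "simulate")
        bundle = io.load_sensor_bundle(pdir)
        ratings = io.read_ratings(pdir / "ratings.csv")
        schedule = estimate_sleep_wake(bundle.acc, bundle.hr, config)
        tables.append(assemble_features(bundle, ratings, schedule, weather,
                                        row.age, config,
                                        participant_id=row.id))
        log.info("extract: %s -> %d rows", row.id, len(tables[-1]))
    table = io.FeatureTable.concat(tables)
    io.write_feature_table(table, workdir / "features.csv")
    io.write_manifest(workdir / "manifest_extract.json", "extract", config,
                      rows=len(table), features=len(feature_names(config)),
                      incomplete=int(table.incomplete_rows().sum()))
    return table


def stage_preprocess(config: RunConfig, workdir) -> io.FeatureTable:
    workdir = Path(workdir)
    table = io.read_feature_table(
        _require(workdir / "features.csv", "extract"), config)
    normalized, stats = preprocess.normalize_per_participant(table)
    imputed_table, imputed_mask = preprocess.impute_zero(normalized)
    io.write_feature_table(imputed_table, workdir / "features_normalized.csv")
    stats.frame.to_csv(workdir / "norm_stats.csv", index=False)
    imputed_mask.to_csv(workdir / "impute_mask.csv", index=False)
    io.write_manifest(workdir / "manifest_preprocess.json", "preprocess",
                      config, rows=len(imputed_table),
                      complete=int((~imputed_table.incomplete_rows()).sum()))
    return imputed_table


def _load_normalized(config: RunConfig, workdir) -> io.FeatureTable:
    return io.read_feature_table(
        _require(Path(workdir) / "features_normalized.csv", "preprocess"),
        config)


def _group_subset(table: io.FeatureTable, participants: pd.DataFrame,
                  group: str) -> io.FeatureTable:
    if group not in GROUP_FILTERS:
        raise ParameterError(f"unknown group {group!r}; "
                             f"use one of {sorted(GROUP_FILTERS)}")
    ids = participants.loc[
        participants["group"].isin(GROUP_FILTERS[group]), "id"]
    rows = table.df["participant_id"].isin(set(ids)).to_numpy()
    out = table.copy()
    out.df = out.df.loc[rows].reset_index(drop=True)
    out.mask = out.mask.loc[rows].reset_index(drop=True)
    return out


def stage_fit(config: RunConfig, workdir, group: str = "all",
              candidates: list[str] | None = None) -> dict:
    workdir = Path(workdir)
    table = _load_normalized(config, workdir)
    participants = io.read_participants(
        _require(workdir / "participants.csv", "simulate"))
    sub = _group_subset(table, participants, group)
    cand = candidates or default_candidates(table, group)
    complete = preprocess.complete_cases(sub)
    log.info("fit[%s]: %d complete rows, %d candidates", group,
             len(complete), len(cand))
    selected, trace = selection.backward_eliminate(
        complete, cand, config, seed=config.seed)
    y = complete.df["vas_norm"].to_numpy(dtype=float)
    result = {"group": group, "candidates": cand, "selected": selected,
              "trace": [
                  {"phase": it.phase, "action": it.action,
                   "removed": it.removed, "mean_edf": it.mean_edf,
                   "mean_p": it.mean_p}
                  for it in trace.iterations]}
    if selected:
        fit = GamDesign(complete.df[selected], y, selected, config).fit()
        result["terms"] = []
        for t in fit.terms:
            curve = partial_effect(fit, t.name)
            result["terms"].append({
                "name": t.name, "edf": t.edf, "p_value": t.p_value,
                "shape": classify_shape(curve),
                "grid": curve.grid.tolist(),
                "effect": curve.values.tolist()})
    with open(workdir / f"model_{group}.json", "w") as fh:
        json.dump(result, fh, indent=2, sort_keys=True)
        fh.write("\n")
    io.write_manifest(workdir / f"manifest_fit_{group}.json", "fit", config,
                      group_rows=len(sub), selected=len(selected))
    return result


def _load_selected(workdir, group: str) -> list[str]:
    path = _require(Path(workdir) / f"model_{group}.json", "fit")
    with open(path) as fh:
        return json.load(fh)["selected"]


def stage_evaluate(config: RunConfig, workdir, train: str = "all",
                   test: str | None = None) -> pd.DataFrame:
    workdir = Path(workdir)
    test = test or train
    table = _load_normalized(config, workdir)
    participants = io.read_participants(
        _require(workdir / "participants.csv", "simulate"))
    terms = _load_selected(workdir, train)
    train_tab = _group_subset(table, participants, train)
    test_tab = _group_subset(table, participants, test)
    baseline = evaluation.baseline_evaluate(test_tab, group=test)
    p_within = p_within_imp = np.nan
    if train == test:
        res = evaluation.lopo_evaluate(train_tab, terms, config, group=train)
    else:
        res = evaluation.across_group_evaluate(
            train_tab, test_tab, terms, config,
            train_group=train, test_group=test)
        # Wilcoxon: is across-group performance different from the test
        # group's own within-group (LOPO) performance?
        test_model = Path(workdir) / f"model_{test}.json"
        if test_model.exists():
            within = evaluation.lopo_evaluate(
                test_tab, _load_selected(workdir, test), config, group=test)
            if res.n_participants >= 5:
                p_within = evaluation.compare_wilcoxon(
                    res.metric_values("r2", "cc"),
                    within.metric_values("r2", "cc"))
                p_within_imp = evaluation.compare_wilcoxon(
                    res.metric_values("r2", "imp"),
                    within.metric_values("r2", "imp"))
    row = {
        "train": train, "test": test,
        "n_participants": res.n_participants,
        "n_rows": res.n_rows_all,
        "r2_cc": res.group_mean("r2", "cc"),
        "mae_cc": res.group_mean("mae", "cc"),
        "rmse_cc": res.group_mean("rmse", "cc"),
        "r2_imp": res.group_mean("r2", "imp"),
        "mae_imp": res.group_mean("mae", "imp"),
        "rmse_imp": res.group_mean("rmse", "imp"),
        "baseline_r2": baseline.group_mean("r2", "cc"),
        "baseline_mae": baseline.group_mean("mae", "cc"),
        "baseline_rmse": baseline.group_mean("rmse", "cc"),
        "p_vs_within": p_within,
        "p_vs_within_imp": p_within_imp,
    }
    out_path = workdir / "evaluation.csv"
    existing = pd.read_csv(out_path) if out_path.exists() else pd.DataFrame()
    out = pd.concat([existing, pd.DataFrame([row])], ignore_index=True)
    out = out.drop_duplicates(subset=["train", "test"], keep="last")
    out.to_csv(out_path, index=False)
    io.write_manifest(workdir / f"manifest_evaluate_{train}_{test}.json",
                      "evaluate", config, rows=res.n_rows_all,
                      participants=res.n_participants)
    return out


def stage_ablate(config: RunConfig, workdir, group: str = "all",
                 candidates: list[str] | None = None) -> pd.DataFrame:
    workdir = Path(workdir)
    table = _load_normalized(config, workdir)
    participants = io.read_participants(
        _require(workdir / "participants.csv", "simulate"))
    sub = _group_subset(table, participants, group)
    cand = candidates or default_candidates(table, group)
    result = evaluation.ablation_study(sub, cand, config, seed=config.seed)
    result.table.to_csv(workdir / f"ablation_{group}.csv", index=False)
    io.write_manifest(workdir / f"manifest_ablate_{group}.json", "ablate",
                      config, configurations=len(result.table))
    return result.table


def run_pipeline(config: RunConfig, stage: str, workdir,
                 spec: synthetic.CohortSpec | None = None, **kwargs):
    """Dispatch a single stage by name (see :data:`STAGES`)."""
    if stage not in STAGES:
        raise ParameterError(f"unknown stage {stage!r}; use one of {STAGES}")
    if stage == "simulate":
        return stage_simulate(config, spec or synthetic.CohortSpec(), workdir)
    if stage == "extract":
        return stage_extract(config, workdir)
    if stage == "preprocess":
        return stage_preprocess(config, workdir)
    if stage == "fit":
        return stage_fit(config, workdir, **kwargs)
    if stage == "evaluate":
        return stage_evaluate(config, workdir, **kwargs)
    return stage_ablate(config, workdir, **kwargs)
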