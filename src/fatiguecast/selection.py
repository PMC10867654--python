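"""Subsample backward elimination of smooth terms.

At each iteration the model with all current candidates is refitted on many
subsamples of the data, each excluding all rows of two randomly chosen
participants.  Per candidate, the effective degrees of freedom and p-values
are averaged across subsamples; then

1. every candidate whose mean EDF falls below the EDF threshold is purged at
   once (its effect was shrunk to nothing on most subsamples), else
2. if any candidate's mean p exceeds the p threshold, the single candidate
   with the highest mean p is removed (ties break to the lexicographically
   last name), else
3. the loop stops.

Afterwards the model is refitted on all participants and the two rules are
re-applied on full-data fits until neither triggers.  Selection runs on
complete cases (no imputed rows).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import FatiguecastError, RunConfig
from .gam import GamDesign
from .io import FeatureTable


@dataclass
class IterationRecord:
    phase: str                      # "subsample" or "full"
    candidates: list[str]
    mean_edf: dict[str, float]
    mean_p: dict[str, float]
    action: str                     # "edf_purge" | "p_removal" | "stop"
    removed: list[str]


@dataclass
class EliminationTrace:
    iterations: list[IterationRecord] = field(default_factory=list)

    def removed_terms(self) -> list[str]:
        out: list[str] = []
        for it in self.iterations:
            out += it.removed
        return out


def _apply_rules(candidates, mean_edf, mean_p, config):
    """One application of the purge/removal rules.  Returns (action,
    removed)."""
    purge = [c for c in candidates if mean_edf[c] < config.edf_threshold]
    if purge:
        return "edf_purge", purge
    over = {c: mean_p[c] for c in candidates
            if mean_p[c] > config.p_threshold}
    if over:
        worst = max(over.values())
        tied = sorted(c for c, p in over.items() if p >= worst - 1e-12)
        return "p_removal", [tied[-1]]
    return "stop", []


def backward_eliminate(data: FeatureTable, candidates: list[str],
                       config: RunConfig | None = None,
                       seed: int | None = None,
                       method: str | None = None
                       ) -> tuple[list[str], EliminationTrace]:
    """Run the elimination loop on complete-case normalized data.

    Parameters
    ----------
    data
        Feature table with a ``vas_norm`` response column; rows must be
        complete on all candidate columns.
    seed
        Seeds the subsample draws (defaults to ``config.seed``).

    Returns the selected term names (input order preserved) and the full
    audit trail.
    """
    config = config or RunConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pids = data.df["participant_id"].to_numpy()
    unique_pids = np.array(sorted(set(pids)))
    if unique_pids.size < 4:
        raise FatiguecastError(
            f"elimination needs >= 4 participants, got {unique_pids.size}")
    y = data.df["vas_norm"].to_numpy(dtype=float)
    trace = EliminationTrace()
    current = list(candidates)

    while current:
        design = GamDesign(data.df[current], y, current, config)
        lam_ref = design.fit(method=method).lambdas
        edf_acc = {c: [] for c in current}
        p_acc = {c: [] for c in current}
        for _ in range(config.n_subsamples):
            excl = rng.choice(unique_pids, size=2, replace=False)
            rows = ~np.isin(pids, excl)
            fit = design.fit(rows=rows, method=method, lam0=lam_ref)
            for t in fit.terms:
                edf_acc[t.name].append(t.edf)
                p_acc[t.name].append(t.p_value)
        mean_edf = {c: float(np.mean(v)) for c, v in edf_acc.items()}
        mean_p = {c: float(np.mean(v)) for c, v in p_acc.items()}
        action, removed = _apply_rules(current, mean_edf, mean_p, config)
        trace.iterations.append(IterationRecord(
            "subsample", list(current), mean_edf, mean_p, action, removed))
        if action == "stop":
            break
        current = [c for c in current if c not in removed]

    # final phase: full-data fits, same rules, to a fixed point
    while current:
        design = GamDesign(data.df[current], y, current, config)
        fit = design.fit(method=method)
        edf = {t.name: t.edf for t in fit.terms}
        pv = {t.name: t.p_value for t in fit.terms}
        action, removed = _apply_rules(current, edf, pv, config)
        trace.iterations.append(IterationRecord(
            "full", list(current), edf, pv, action, removed))
        if action == "stop":
            break
        current = [c for c in current if c not in removed]

    return current, trace
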