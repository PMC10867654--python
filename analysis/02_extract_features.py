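#!/usr/bin/env python
"""Extract per-rating features across the five time horizons.

Reads the cohort written by 01_simulate_cohort.py, re-estimates sleep/wake
from acceleration + heart rate, and writes results/cohort/features.csv
(~200 features per rating with explicit missingness masks).
"""

import sys
import warnings
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))
warnings.simplefilter("ignore")

import fatiguecast as fc
from fatiguecast import pipeline

WORKDIR = Path(__file__).resolve().parent.parent / "results" / "cohort"
CONFIG = fc.RunConfig(seed=1, smooth_criterion="efs", n_subsamples=50)

if __name__ == "__main__":
    table = pipeline.stage_extract(CONFIG, WORKDIR)
    n_miss = table.incomplete_rows().sum()
    print(f"extracted {len(table)} feature vectors "
          f"({len(table.feature_names)} features each); "
          f"{n_miss} rows have at least one missing feature")
    by_group = {}
    for f in table.feature_names:
        by_group.setdefault(table.groups[f], []).append(f)
    for g, feats in sorted(by_group.items()):
        print(f"  {g}: {len(feats)} features")
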