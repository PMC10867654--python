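#!/usr/bin/env python
"""Feature-group ablation for the MS-dysfunctional-ANS group.

Re-runs selection + LOPO under the ten feature-subset configurations (all
groups, minus each, only each, routine only) and tests each against the
routine-only reference with paired Wilcoxon tests over participant
perturbations.  Writes results/cohort/ablation_ms2.csv.
"""

import sys
import warnings
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))
warnings.simplefilter("ignore")

import fatiguecast as fc
from fatiguecast import pipeline

WORKDIR = Path(__file__).resolve().parent.parent / "results" / "cohort"
CONFIG = fc.RunConfig(seed=1, smooth_criterion="efs", n_subsamples=30,
                      n_perturbations=30)

if __name__ == "__main__":
    table = pipeline.stage_ablate(CONFIG, WORKDIR, group="ms2")
    print(table.to_string(index=False,
                          float_format=lambda v: f"{v:.2f}"))
    ref = table.loc[table["config"] == "routine_only",
                    "mean_r2_cc"].iloc[0]
    best = table.loc[table["mean_r2_cc"].idxmax()]
    print(f"\nroutine-only reference R2 {ref:.1f}%; best configuration "
          f"{best['config']} at {best['mean_r2_cc']:.1f}%")
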