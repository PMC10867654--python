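#!/usr/bin/env python
"""Within-group (leave-one-participant-out) and across-group evaluation.

Each group's selected model is evaluated by LOPO on its own group and
transferred to the other groups, always against the per-participant-mean
baseline (R^2 = 0 by construction).  Appends rows to
results/cohort/evaluation.csv in the train/test layout.
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

PAIRS = [("co", "co"), ("ms1", "ms1"), ("ms2", "ms2"),
         ("co", "ms2"), ("ms1", "ms2"), ("ms2", "ms1")]

if __name__ == "__main__":
    out = None
    for train, test in PAIRS:
        out = pipeline.stage_evaluate(CONFIG, WORKDIR, train=train,
                                      test=test)
        row = out[(out["train"] == train) & (out["test"] == test)].iloc[-1]
        kind = "LOPO" if train == test else "transfer"
        print(f"{train:>4} -> {test:<4} ({kind:8}) "
              f"R2 {row['r2_cc']:6.1f}%  MAE {row['mae_cc']:.2f}  "
              f"baseline R2 {row['baseline_r2']:.0f}")
    print(f"\nfull table in {WORKDIR / 'evaluation.csv'}")
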