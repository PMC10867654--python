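#!/usr/bin/env python
"""Per-participant normalization and zero imputation.

Z-scores every feature and the VAS rating within each participant
(population SD over the full study, ignoring missing values), imputes
missing cells with zero (= the participant mean), and writes
features_normalized.csv, norm_stats.csv and impute_mask.csv.
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
    table = pipeline.stage_preprocess(CONFIG, WORKDIR)
    complete = (~table.incomplete_rows()).sum()
    print(f"{len(table)} rows normalized; {complete} complete cases "
          f"({100 * complete / len(table):.0f}%) form the training set")
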