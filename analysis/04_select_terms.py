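#!/usr/bin/env python
"""Subsample backward elimination per participant group.

For each group (controls, MS with functional ANS, MS with dysfunctional
ANS) the shrinkage GAM is refitted on many subsamples, each excluding two
participants; terms whose smooths are shrunk away (mean EDF < 0.1) are
purged and the least significant term (mean p > 0.05) is dropped until all
survivors are stable and significant.  Writes model_<group>.json with the
selected terms, their partial-effect curves and shape labels.
"""

import json
import sys
import warnings
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))
warnings.simplefilter("ignore")

import fatiguecast as fc
from fatiguecast import pipeline
from fatiguecast.gam import SHAPE_SYMBOLS

WORKDIR = Path(__file__).resolve().parent.parent / "results" / "cohort"
CONFIG = fc.RunConfig(seed=1, smooth_criterion="efs", n_subsamples=50)

if __name__ == "__main__":
    for group in ("co", "ms1", "ms2"):
        result = pipeline.stage_fit(CONFIG, WORKDIR, group=group)
        print(f"[{group}] selected {len(result['selected'])} of "
              f"{len(result['candidates'])} candidates:")
        for term in result.get("terms", []):
            sym = SHAPE_SYMBOLS[term["shape"]]
            print(f"    {term['name']:<22} edf {term['edf']:.2f}  "
                  f"p {term['p_value']:.3g}  shape {sym}")
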