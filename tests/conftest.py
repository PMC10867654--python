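import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import fatiguecast as fc
from fatiguecast.synthetic import CohortSpec, generate_cohort

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fast_config() -> fc.RunConfig:
    """Light settings for simulation-heavy paths: REML-like smoothing
    updates and reduced subsample counts."""
    return fc.RunConfig(smooth_criterion="efs", n_subsamples=25,
                        n_perturbations=20)


@pytest.fixture(scope="session")
def small_cohort():
    """Six participants (2 per group), 5 rating days, the default ground
    truth and 25% injected missingness."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(CohortSpec(n_co=2, n_ms1=2, n_ms2=2,
                                          days=5, seed=7))


@pytest.fixture(scope="session")
def clean_cohort():
    """Four participants, no injected missingness, single time-of-day
    effect at low noise — used for trend and completeness checks."""
    from fatiguecast.synthetic import Effect, TruthModel
    truth = TruthModel(
        effects={g: [Effect("time_of_day", "rise", 0.8)]
                 for g in ("CO", "MS_I", "MS_II")},
        noise_sd=0.2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(
            CohortSpec(n_co=2, n_ms1=1, n_ms2=1, days=5,
                       missing_rate=0.0, noise_sd=0.2, seed=21),
            truth=truth)
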