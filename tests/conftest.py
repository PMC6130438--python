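import numpy as np
import pytest

import ezloc

#: Seed of the session-wide synthetic cohort experiments.
COHORT_SEED = 7


@pytest.fixture(scope="session")
def small_recording():
    """A small but complete synthetic seizure clip (16 channels, 40 s)."""
    cfg = ezloc.SynthConfig(
        n_channels=16, ez_size=4, pre_s=12.0, ictal_s=16.0, post_s=12.0,
        seed=3,
    )
    rec, planted = ezloc.generate_recording(cfg)
    return rec, planted, cfg


@pytest.fixture(scope="session")
def cohort_experiment():
    """Full-scale held-out localization experiment, computed once.

    A 16-patient cohort (8 successful, 8 failed outcomes, ~80 channels,
    240-s clips, two seizures each); the weighting function is trained
    on 8 patients and evaluated on the held-out 8 at alpha = 0.9.
    """
    cohort = ezloc.generate_cohort(n_patients=16, seed=COHORT_SEED)
    features = ezloc.cohort_features(cohort)
    experiment = ezloc.holdout_experiment(
        cohort, n_train=8, alpha=0.9, features=features
    )
    planted = {
        p.patient_id: frozenset(
            f"CH{i + 1:03d}" for i in p.seizure_configs[0].ez_channels
        )
        for p in cohort.patients
    }
    return {
        "cohort": cohort,
        "features": features,
        "experiment": experiment,
        "planted": planted,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
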