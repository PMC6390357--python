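import warnings

import pandas as pd
import pytest

from illdeath.prep import TransitionDataset, build_transition_datasets
from illdeath.synthetic import paper_like_config, simulate_illness_death


@pytest.fixture(autouse=True)
def _silence_epv_warnings():
    """The small test cohorts routinely trip the events-per-covariate
    guard; that warning is tested explicitly where it matters."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*events/15.*")
        warnings.filterwarnings("ignore", message=".*covariates for.*")
        yield


@pytest.fixture(scope="session")
def cohort():
    """One registry-like cohort without missingness (session-cached)."""
    return simulate_illness_death(paper_like_config(seed=42))


@pytest.fixture(scope="session")
def datasets(cohort):
    return build_transition_datasets(cohort.lesions, cohort.patients)


@pytest.fixture()
def two_subject_dataset():
    """The minimal hand-checkable Cox dataset: two subjects, both events,
    at times 1 and 2, covariate values 1 and 0, one cluster."""
    frame = pd.DataFrame({
        "cluster": [1, 1],
        "entry": [0.0, 0.0],
        "exit": [1.0, 2.0],
        "event": [1, 1],
        "x": [1.0, 0.0],
    })
    return TransitionDataset(1, frame, ["x"])


def make_lesion_dataset(cfg, cohort, covariate="bed_std"):
    """Transition-1 counting-process frame on the generator's own
    standardisation scale (for parameter-recovery checks)."""
    l = cohort.lesions
    frame = pd.DataFrame({
        "cluster": l["hospital_id"].to_numpy(),
        "entry": 0.0,
        "exit": l["time_lc"].to_numpy(dtype=float),
        "event": l["event_lc"].to_numpy(dtype=int),
        "bed_std": (l["bed_iso"].to_numpy(dtype=float) - cfg.bed_center) / cfg.bed_scale,
    })
    return TransitionDataset(1, frame, [covariate])
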