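import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True)
settings.load_profile("reproducible")

from pupilsdt.synth import (
    CohortConfig,
    Paradigm,
    generate_cohort,
    generate_session,
)


def make_trials(stimuli, outcomes, rts=None, impulsive=None, spacing=11.0):
    """Hand-build a minimal trial table."""
    n = len(stimuli)
    rts = rts if rts is not None else [np.nan] * n
    impulsive = impulsive if impulsive is not None else [False] * n
    onsets = spacing * np.arange(n) + 2.5
    return pd.DataFrame(
        {
            "index": np.arange(n),
            "stimulus": stimuli,
            "outcome": outcomes,
            "reaction_time": rts,
            "impulsive_lick": impulsive,
            "stimulus_onset": onsets,
            "trial_end": onsets + spacing - 2.5,
        }
    )


@pytest.fixture(scope="session")
def session_05():
    """One medium-sized balanced-paradigm session."""
    return generate_session(Paradigm(go_fraction=0.5, n_trials=270), seed=42)


@pytest.fixture(scope="session")
def small_cohort():
    """Nine short sessions, three per paradigm (round robin)."""
    cfg = CohortConfig(go_fractions=(0.8, 0.5, 0.2), n_sessions=9, n_trials=120)
    return generate_cohort(cfg, master_seed=5)
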