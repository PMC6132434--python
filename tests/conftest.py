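import numpy as np
import pandas as pd
import pytest

from isosub import simulate as S


def make_series(counts, person_id="p", start="2005-06-06", epoch_length=60):
    """Epoch series from a plain count vector starting at midnight."""
    counts = np.asarray(counts, dtype=np.int64)
    ts = pd.date_range(start, periods=len(counts), freq=f"{epoch_length}s")
    from isosub.epochs import EpochSeries
    return EpochSeries(person_id, epoch_length, ts, counts)


def noiseless_config(seed=0, n_studies=5, persons_per_study=60):
    """Planted waist-circumference model with all variance components zero."""
    return S.SimulationConfig(
        n_studies=n_studies, persons_per_study=persons_per_study,
        study_intercept_sd={"wc": 0.0}, residual_sd={"wc": 0.0}, seed=seed)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Deterministic-outcome cohort: outcomes are an exact linear function
    of behaviours and sex, no study or residual noise."""
    return S.simulate_dataset(noiseless_config())


@pytest.fixture(scope="session")
def noisy_cohort():
    cfg = S.SimulationConfig(n_studies=13, persons_per_study=60, seed=11)
    return S.simulate_dataset(cfg)
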