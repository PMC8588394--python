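import numpy as np
import pytest
from hypothesis import settings

from glybench import SimConfig, inject_gaps, simulate_patient
from glybench.series import PatientSeries

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(n_patients=2, days=4, seed=11)


@pytest.fixture(scope="session")
def patient(sim_config):
    """One simulated patient with sensor gaps injected."""
    return inject_gaps(simulate_patient(sim_config, 0), sim_config)


@pytest.fixture(scope="session")
def clean_patient(sim_config):
    return simulate_patient(sim_config, 0)


def make_series(bg, bas=None, bol=None, ch=None, test_tail=0, scaled=False):
    """Construct a small PatientSeries for unit tests."""
    bg = np.asarray(bg, dtype=float)
    n = len(bg)
    zeros = np.zeros(n)
    split = np.array(
        ["train"] * (n - test_tail) + ["test"] * test_tail, dtype=object
    )
    return PatientSeries(
        patient_id="unit",
        timestamps=np.arange(n, dtype=float) * 5.0,
        bg=bg,
        bas=zeros if bas is None else np.asarray(bas, float),
        bol=zeros if bol is None else np.asarray(bol, float),
        ch=zeros if ch is None else np.asarray(ch, float),
        split=split,
        scaled=scaled,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
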