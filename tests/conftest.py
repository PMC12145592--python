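import numpy as np
import pandas as pd
import pytest

from nirferm import (
    CONSTITUENTS,
    ConcentrationTable,
    SpectralAxis,
    SpectraSet,
    build_default_library,
    default_profiles,
)


def make_meta(n, experiment="E1", prefix="S"):
    return pd.DataFrame({
        "sample_id": [f"{prefix}{i}" for i in range(n)],
        "experiment_id": experiment,
        "time_h": np.arange(n, dtype=float),
        "instrument": "lab_grade",
        "modality": "at_line",
        "vessel_volume_L": 0.5,
    })


def make_spectra(n=5, p=12, seed=0, lo=4000.0, hi=4550.0):
    rng = np.random.default_rng(seed)
    axis = SpectralAxis(np.linspace(lo, hi, p), "cm-1")
    return SpectraSet(axis, rng.normal(1.0, 0.2, size=(n, p)), make_meta(n))


def make_conc(n=5, seed=0, c_max=60.0, **extra):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.uniform(0, c_max, size=(n, 5)), columns=CONSTITUENTS)
    df.insert(0, "sample_id", [f"S{i}" for i in range(n)])
    for k, v in extra.items():
        df[k] = v
    return ConcentrationTable(df)


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def library():
    return build_default_library()


@pytest.fixture
def rng():
    return np.random.default_rng(42)
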