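import numpy as np
import pandas as pd
import pytest

from eegbattery.cohort import CohortConfig, generate_demographics
from eegbattery.layout import ChannelLayout, default_layout
from eegbattery.registry import build_registry


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def registry(layout):
    return build_registry(layout)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def toy_layout():
    """Eight channels spread over the upper hemisphere (for Laplacian tests)."""
    angles = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    incl = np.deg2rad(60.0)
    positions = np.column_stack(
        [np.sin(incl) * np.cos(angles), np.sin(incl) * np.sin(angles), np.full(8, np.cos(incl))]
    )
    return ChannelLayout(
        names=tuple(f"ch{i}" for i in range(8)),
        positions=positions,
        region=("frontal",) * 4 + ("occipital",) * 4,
        hemisphere=("left", "right") * 4,
    )


@pytest.fixture(scope="session")
def cohort_demo():
    """A 300-participant demographics table (100 per age stratum)."""
    cfg = CohortConfig(
        n_per_stratum={"AD": (15, 15, 15), "ASD": (15, 15, 15), "CON": (70, 70, 70)}
    )
    return generate_demographics(cfg, seed=7)


def make_demographics(n, seed=0, female_fraction=0.5, diagnoses=("AD", "ASD", "CON")):
    """Small ad-hoc demographics frame for unit tests."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "participant_id": [f"p{i:03d}" for i in range(n)],
            "age_months": rng.uniform(3, 248, n),
            "sex": rng.choice(["F", "M"], n, p=[female_fraction, 1 - female_fraction]),
            "iq": rng.normal(100, 15, n),
            "diagnosis": [diagnoses[i % len(diagnoses)] for i in range(n)],
            "dataset": "test",
        }
    )
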