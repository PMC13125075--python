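"""Shared fixtures: small synthetic cohorts and on-disk layouts."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gradsuite import CohortSpec, make_parcellation

#: reduced-size study conditions for fast end-to-end tests: the same
#: 7-network structure at 80 parcels with 8 insula parcels
SMALL_SIZES = {"VN": 12, "SMN": 15, "DAN": 9, "SN": 14, "LN": 5,
               "CN": 10, "DMN": 15}


@pytest.fixture(scope="session")
def default_spec() -> CohortSpec:
    return CohortSpec()


@pytest.fixture(scope="session")
def default_scheme(default_spec):
    return make_parcellation(default_spec)


@pytest.fixture()
def small_spec() -> CohortSpec:
    return CohortSpec(n_parcels=80, network_sizes=dict(SMALL_SIZES),
                      n_insula=8, n_mdd=8, n_hc=7, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_cohort() -> pd.DataFrame:
    r = np.random.default_rng(5)
    n = 40
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "group": ["MDD"] * 20 + ["HC"] * 20,
        "age": r.normal(38, 11, n).round(1),
        "gender": r.choice(["F", "M"], n),
        "hamd": np.abs(r.normal(15, 8, n)).astype(int),
    })


def random_affinity(rng: np.random.Generator, n: int) -> np.ndarray:
    """A valid normalized-angle-style affinity: symmetric, [0,1], unit diag."""
    from gradsuite import normalized_angle_affinity
    return normalized_angle_affinity(rng.random((n, n + 3)))
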