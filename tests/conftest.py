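import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

import maskgap as mg

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass

SERVICE_RATE = 0.033  # adults served per capita per day, study-area scale


@pytest.fixture(scope="session")
def small_cfg():
    return mg.SyntheticConfig(
        n_villages=60, n_stores=30, region_size=12_000.0, seed=7, n_days=3
    )


@pytest.fixture(scope="session")
def small_villages(small_cfg):
    """Villages with E attached and BYM-simulated counts, plus the truth."""
    vil = mg.generate_villages(small_cfg)
    vil["E"] = SERVICE_RATE * vil["pop"]
    Y, truth = mg.simulate_counts(vil, small_cfg)
    vil["Y"] = Y
    vil["rho_raw"] = Y / vil["E"]
    return vil, truth


@pytest.fixture(scope="session")
def grid_villages():
    """A 4x4 grid of unit squares: known queen topology."""
    rows = []
    for gy in range(4):
        for gx in range(4):
            rows.append(
                {
                    "village_id": f"G{gy}{gx}",
                    "geometry": box(gx, gy, gx + 1, gy + 1),
                    "pop": 100.0,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def fitted_spatial(small_villages):
    """One warm Poisson-spatial fit shared across tests (also compiles numba)."""
    vil, _ = small_villages
    adj = mg.build_adjacency(vil)
    spec = mg.ModelSpec(
        family="poisson",
        spatial=True,
        chains=2,
        iterations=1200,
        burnin=600,
        thin=2,
        seed=5,
    )
    return mg.fit(spec, vil, adj), vil, adj


def make_intercept_only_frame(n: int, E: float = 100.0) -> pd.DataFrame:
    """Villages whose covariates contribute nothing: Y_i = E_i exactly."""
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        {
            "village_id": [f"I{i:03d}" for i in range(n)],
            "geometry": [box(i, 0, i + 1, 1) for i in range(n)],
            "pop": np.full(n, E),
            "store_count": np.zeros(n),
            "income": np.ones(n),  # log income = 0
            "business_pct": np.zeros(n),
            "residential_pct": np.zeros(n),
            "mixed_pct": np.zeros(n),
            "school_pct": np.zeros(n),
            "E": np.full(n, E),
            "Y": np.full(n, int(E)),
        }
    )
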