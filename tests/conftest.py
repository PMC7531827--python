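import numpy as np
import pytest

from wbcs import (
    SyntheticGridSpec,
    branch_fixtures,
    classify_grid,
    default_ruleset,
    generate_grids,
)


@pytest.fixture(scope="session")
def rs():
    return default_ruleset()


@pytest.fixture(scope="session")
def fixture_grid(rs):
    """Engineered branch-coverage grid and its target labels."""
    return branch_fixtures(rs)


@pytest.fixture(scope="session")
def small_grids():
    """Three noisy synthetic periods at reduced size (same structure)."""
    spec = SyntheticGridSpec(n_cells=400, seed=7)
    return generate_grids(spec)


@pytest.fixture(scope="session")
def small_labels(small_grids, rs):
    return [classify_grid(g, rs) for g in small_grids]


def make_cell_frame(tmin, tmax, prec, lat=48.0, lon=68.0, elev=200.0, cell_id="c1"):
    """Canonical one-row DataFrame from monthly arrays."""
    import pandas as pd

    row = {"cell_id": cell_id, "lat": lat, "lon": lon, "elev_m": elev}
    for j in range(12):
        row[f"tmin_{j + 1:02d}"] = tmin[j]
    for j in range(12):
        row[f"tmax_{j + 1:02d}"] = tmax[j]
    for j in range(12):
        row[f"prec_{j + 1:02d}"] = prec[j]
    return pd.DataFrame([row])


def random_cells(n, seed):
    """Physically plausible random monthly climatologies."""
    rng = np.random.default_rng(seed)
    tmean = rng.uniform(-12, 18, n)
    amp = rng.uniform(2, 25, n)
    phase = rng.integers(0, 12, n)
    months = np.arange(12)
    ti = tmean[:, None] + amp[:, None] * np.cos(
        2 * np.pi * (months[None, :] - phase[:, None]) / 12
    )
    diurnal = rng.uniform(2, 8, n)[:, None]
    prec = rng.gamma(1.2, 18.0, size=(n, 12))
    lat = rng.uniform(-70, 70, n)
    elev = rng.uniform(0, 3500, n)
    return ti - diurnal, ti + diurnal, prec, lat, elev
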