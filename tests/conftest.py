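import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def all_cover_raster():
    from fidescape import Point, VegetationRaster
    return VegetationRaster(origin=Point(0.0, 0.0), cell_size=1.0,
                            cells=np.ones((60, 60), dtype=bool))


@pytest.fixture
def all_open_raster():
    from fidescape import Point, VegetationRaster
    return VegetationRaster(origin=Point(0.0, 0.0), cell_size=1.0,
                            cells=np.zeros((60, 60), dtype=bool))


@pytest.fixture
def halfplane_raster():
    """Vegetated exactly on the half-plane x >= 15, 60 x 60 m."""
    from fidescape import Point, VegetationRaster
    cells = np.zeros((60, 60), dtype=bool)
    cells[:, 15:] = True
    return VegetationRaster(origin=Point(0.0, 0.0), cell_size=1.0, cells=cells)


def toy_encounters(n=30, seed=0):
    """Small valid encounter table with complete rows."""
    rng = np.random.default_rng(seed)
    n_park = 3
    std = rng.uniform(15, 50, n)
    fid = np.clip(4 + 0.3 * std + rng.normal(0, 2, n), 1, std - 0.5)
    return pd.DataFrame({
        "species": ["sp_a"] * n,
        "park_id": [f"P{i % n_park}" for i in range(n)],
        "std_m": std,
        "fid_m": fid,
        "responded": True,
        "escape_mode": "fly",
        "x0": rng.uniform(0, 500, n), "y0": rng.uniform(0, 500, n),
        "x1": rng.uniform(0, 500, n), "y1": rng.uniform(0, 500, n),
        "distance_fled_m": rng.uniform(6, 40, n),
    })
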