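import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from trophiclink import synthgrid

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def bottom_up_truth():
    """One small bottom-up landscape shared across read-only tests."""
    cfg = synthgrid.scenario("bottom_up", n_cells_x=3, n_cells_y=3, years=20, seed=11)
    return synthgrid.simulate_latent_dynamics(cfg, synthgrid.simulate_weather(cfg))


@pytest.fixture(scope="session")
def bottom_up_panel(bottom_up_truth):
    return synthgrid.truth_panel(bottom_up_truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_paired_panel(rng, n_cells=6, years=12, scale_m=100_000, missing=0.0):
    """Random paired panel in the PairedPanelTable schema (test helper)."""
    rows = []
    for c in range(n_cells):
        ix, iy = c % 3, c // 3
        for t in range(years):
            if rng.random() < missing:
                continue
            rows.append((
                scale_m, ix, iy, 2000 + t,
                rng.gamma(4, 2), rng.gamma(4, 2),
                rng.normal(9, 1), rng.normal(900, 40),
                (ix * scale_m) // 100_000, (iy * scale_m) // 100_000,
            ))
    return pd.DataFrame(rows, columns=[
        "scale_m", "ix", "iy", "year", "insectivore_value", "insect_value",
        "temp_annual", "precip_annual", "region_ix", "region_iy",
    ])
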