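"""Nested grid assignment, cell-level aggregation and series pairing.

Sites live on planar national-grid coordinates (metres).  A cell at scale
``s`` is simply ``(floor(easting/s), floor(northing/s))``, so cells nest:
every 10 km cell has a unique 50 km and 100 km ancestor.  Site indices are
averaged per cell and year, and insectivore/insect/weather series are
paired on cell x year into the common panel consumed by all three
analysis tiers.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

SCALES_M = (100_000, 50_000, 10_000)
WEATHER_COLS = [
    "temp_spring", "precip_spring", "temp_summer", "precip_summer",
    "temp_winter", "precip_winter", "temp_annual", "precip_annual",
]


class GridCellId(NamedTuple):
    scale_m: int
    ix: int
    iy: int

    def parent(self, scale_m: int) -> "GridCellId":
        """The unique ancestor cell at a coarser scale."""
        if scale_m < self.scale_m:
            raise ValidationError(f"parent scale {scale_m} finer than {self.scale_m}")
        return GridCellId(
            scale_m,
            (self.ix * self.scale_m) // scale_m,
            (self.iy * self.scale_m) // scale_m,
        )


def assign_cell(easting_m: float, northing_m: float, scale_m: int) -> GridCellId:
    if easting_m < 0 or northing_m < 0:
        raise ValidationError(
            f"negative coordinate ({easting_m}, {northing_m}); planar grid coordinates must be >= 0"
        )
    return GridCellId(int(scale_m), int(easting_m // scale_m), int(northing_m // scale_m))


def aggregate_to_cells(indices: pd.DataFrame, scale_m: int) -> pd.DataFrame:
    """Average site indices per cell and year (unweighted arithmetic mean).

    Returns long-format cell series: one row per cell x taxon x year with
    the mean value and the number of contributing sites; years with no
    sites are simply absent (missing).
    """
    if indices.empty:
        raise ValidationError("site index table is empty")
    if (indices[["easting_m", "northing_m"]] < 0).any().any():
        raise ValidationError("negative coordinates in site index table")
    df = indices.copy()
    df["ix"] = (df["easting_m"] // scale_m).astype(int)
    df["iy"] = (df["northing_m"] // scale_m).astype(int)
    out = df.groupby(["ix", "iy", "taxon", "year"], as_index=False).agg(
        value=("value", "mean"), n_sites=("value", "size")
    )
    out.insert(0, "scale_m", int(scale_m))
    return out.sort_values(["taxon", "ix", "iy", "year"]).reset_index(drop=True)


def _weather_wide(weather: pd.DataFrame) -> pd.DataFrame:
    """Pivot the seasonal weather table to one row per 100 km cell x year."""
    wide = weather.pivot_table(
        index=["ix", "iy", "year"], columns="season",
        values=["mean_temp_c", "total_precip_mm"],
    )
    wide.columns = [
        ("temp_" if a == "mean_temp_c" else "precip_") + b for a, b in wide.columns
    ]
    return wide.reset_index().rename(columns={"ix": "region_ix", "iy": "region_iy"})


def pair_series(
    insectivore: pd.DataFrame,
    insect: pd.DataFrame,
    weather: pd.DataFrame,
    pairing: tuple[str, str],
) -> pd.DataFrame:
    """Inner-join insectivore and insect cell series on cell x year.

    Weather (held at the 100 km scale) is joined through each cell's 100 km
    ancestor, which is also recorded as the ``region`` used for clustered
    standard errors.
    """
    tax_a, tax_b = pairing
    a = insectivore[insectivore["taxon"] == tax_a]
    b = insect[insect["taxon"] == tax_b]
    if a.empty or b.empty:
        raise ValidationError(f"no cell series for pairing {pairing}")
    scales = set(a["scale_m"]).union(b["scale_m"])
    if len(scales) != 1:
        raise ValidationError(f"scale mismatch between paired series: {sorted(scales)}")
    scale_m = scales.pop()

    merged = a.merge(
        b, on=["scale_m", "ix", "iy", "year"], suffixes=("_insectivore", "_insect")
    )
    if merged.empty:
        logger.warning("pair_series: no overlapping cells/years for pairing %s", pairing)
    merged = merged.rename(
        columns={
            "value_insectivore": "insectivore_value",
            "value_insect": "insect_value",
            "n_sites_insectivore": "n_sites_insectivore",
            "n_sites_insect": "n_sites_insect",
        }
    )
    merged["region_ix"] = (merged["ix"] * scale_m) // 100_000
    merged["region_iy"] = (merged["iy"] * scale_m) // 100_000
    wide = _weather_wide(weather)
    merged = merged.merge(wide, on=["region_ix", "region_iy", "year"], how="left")
    cols = [
        "scale_m", "ix", "iy", "year", "insectivore_value", "insect_value",
        "n_sites_insectivore", "n_sites_insect", "region_ix", "region_iy",
    ] + [c for c in WEATHER_COLS if c in merged.columns]
    return merged[cols].sort_values(["ix", "iy", "year"]).reset_index(drop=True)


def standardize(values) -> np.ndarray:
    """Z-score over non-missing entries (mean 0, SD 1, denominator n-1)."""
    x = np.asarray(values, dtype=float)
    obs = x[~np.isnan(x)]
    if len(obs) < 2:
        raise ValidationError("standardize requires >= 2 non-missing values")
    sd = obs.std(ddof=1)
    if sd == 0:
        raise ValidationError("standardize: zero variance")
    return (x - obs.mean()) / sd
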