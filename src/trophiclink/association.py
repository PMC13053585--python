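"""Tier 1 — associative diagnostics on paired cell series.

Each annual cell series is split into a smooth long-term trend (loess:
tricube-weighted local linear regression with robustness iterations) and a
remainder of interannual deviations, with trend + remainder = observed
exactly.  Spatial agreement of trend directions across cells is tested
with an exact binomial sign test, and cross-taxon correlations of the
remainders summarise whether departures from trend co-occur.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import ValidationError

logger = logging.getLogger(__name__)

MIN_DECOMPOSE_YEARS = 5


@dataclass
class Decomposition:
    years: np.ndarray
    observed: np.ndarray
    trend: np.ndarray
    remainder: np.ndarray


@dataclass
class AgreementResult:
    n_cells: int
    k_agree: int
    p_value: float


@dataclass
class RemainderCorrelationSummary:
    correlations: np.ndarray
    mean: float
    ci_low: float
    ci_high: float


def longest_run(
    years, values, min_run: int = 10, max_zero_frac: float = 0.5
):
    """Longest gap-free run of a cell series, or None if it fails the filters.

    A run is a maximal stretch of consecutive calendar years with
    non-missing values.  Runs shorter than ``min_run`` years, or whose zero
    fraction exceeds ``max_zero_frac``, carry too little trend information
    and are discarded.  Ties go to the most recent run.
    """
    years = np.asarray(years, dtype=int)
    values = np.asarray(values, dtype=float)
    ok = ~np.isnan(values)
    years, values = years[ok], values[ok]
    if len(years) == 0:
        return None
    order = np.argsort(years)
    years, values = years[order], values[order]

    breaks = np.flatnonzero(np.diff(years) != 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(years) - 1]])
    lengths = ends - starts + 1
    best = max(range(len(starts)), key=lambda i: (lengths[i], years[starts[i]]))
    ys = years[starts[best]: ends[best] + 1]
    vs = values[starts[best]: ends[best] + 1]
    if len(ys) < min_run:
        return None
    if np.mean(vs == 0) > max_zero_frac:
        return None
    return ys, vs


def decompose(years, values, span: float = 0.75) -> Decomposition:
    """Loess trend + remainder decomposition of an annual series.

    The trend is a tricube-weighted local linear regression (two robustness
    iterations); the smoothing window always covers at least five points.
    The remainder is defined as observed minus trend, so the additive
    identity holds exactly by construction.
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < MIN_DECOMPOSE_YEARS:
        raise ValidationError(f"decompose requires >= {MIN_DECOMPOSE_YEARS} years, got {n}")
    frac = max(float(span), min(1.0, MIN_DECOMPOSE_YEARS / n))
    # Smooth the residuals of the global OLS line and add the line back:
    # identical in exact arithmetic (the local linear smoother reproduces
    # lines), but keeps linear series numerically exact at large x values.
    xc = years - years.mean()
    b = (xc * values).sum() / (xc ** 2).sum()
    line = values.mean() + b * xc
    trend = line + lowess(values - line, xc, frac=frac, it=2, return_sorted=False)
    return Decomposition(
        years=years.astype(int), observed=values, trend=trend, remainder=values - trend
    )


def _ols_slope(years, values):
    """Least-squares slope and its squared standard error."""
    x = np.asarray(years, float)
    y = np.asarray(values, float)
    xc = x - x.mean()
    sxx = (xc ** 2).sum()
    b = (xc * y).sum() / sxx
    resid = y - y.mean() - b * xc
    dof = len(x) - 2
    s2 = (resid ** 2).sum() / dof / sxx if dof > 0 else np.nan
    return b, s2


def cell_slopes(cell_series: pd.DataFrame, method: str = "shrunk") -> pd.DataFrame:
    """Per-cell linear trend slopes of value on year.

    ``ols`` fits each cell independently.  ``shrunk`` applies
    method-of-moments empirical-Bayes shrinkage toward the across-cell mean
    slope (between-cell variance estimated as var(slopes) minus the mean
    squared slope SE, floored at zero), a lightweight stand-in for a
    random-slopes mixed model; with a single cell it reduces to OLS.
    Cells with fewer than two distinct years are skipped.
    """
    if method not in ("ols", "shrunk"):
        raise ValidationError(f"unknown slope method {method!r}")
    rows = []
    for (scale, ix, iy), g in cell_series.groupby(["scale_m", "ix", "iy"]):
        g = g.dropna(subset=["value"])
        if g["year"].nunique() < 2:
            logger.info("cell_slopes: skipping cell (%s,%s,%s) with <2 years", scale, ix, iy)
            continue
        b, s2 = _ols_slope(g["year"], g["value"])
        rows.append((scale, ix, iy, b, s2, len(g)))
    out = pd.DataFrame(rows, columns=["scale_m", "ix", "iy", "slope", "var_slope", "n_years"])
    if out.empty:
        return out.assign(sign=pd.Series(dtype=object))
    if method == "shrunk" and len(out) >= 2:
        grand = out["slope"].mean()
        tau2 = max(0.0, out["slope"].var(ddof=1) - np.nanmean(out["var_slope"]))
        w = tau2 / (tau2 + out["var_slope"].fillna(0.0))
        out["slope"] = grand + w * (out["slope"] - grand)
    out["sign"] = np.where(out["slope"] > 0, "increasing", "decreasing")
    out.loc[out["slope"] == 0, "sign"] = "zero"
    return out


def binomial_sign_p(k: int, n: int) -> float:
    """Exact two-sided binomial p at p0 = 0.5: doubled smaller tail, capped at 1."""
    lower = stats.binom.cdf(k, n, 0.5)
    upper = stats.binom.sf(k - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def sign_agreement(slopes_a: pd.DataFrame, slopes_b: pd.DataFrame) -> AgreementResult:
    """Do trend directions of the two taxa agree across cells more than chance?

    Cells are matched on cell id; cells with an exactly zero slope carry no
    direction and are excluded.  Agreement count k over n matched cells is
    referred to an exact Binomial(n, 0.5).
    """
    m = slopes_a.merge(slopes_b, on=["scale_m", "ix", "iy"], suffixes=("_a", "_b"))
    m = m[(m["sign_a"] != "zero") & (m["sign_b"] != "zero")]
    n = len(m)
    if n == 0:
        raise ValidationError("sign_agreement: zero matched cells")
    k = int((m["sign_a"] == m["sign_b"]).sum())
    return AgreementResult(n_cells=n, k_agree=k, p_value=binomial_sign_p(k, n))


def remainder_correlations(
    paired: dict,
    min_overlap: int = 5,
) -> RemainderCorrelationSummary:
    """Per-cell Pearson correlations between the two taxa's remainders.

    ``paired`` maps cell id -> (Decomposition insectivore, Decomposition
    insect).  Correlations are computed over shared years with at least
    ``min_overlap`` observations; cells with a constant remainder vector
    are skipped (undefined r).  The summary is the across-cell mean with a
    t-based 95% confidence interval.
    """
    rs = []
    for cell, (da, db) in paired.items():
        shared, ia, ib = np.intersect1d(da.years, db.years, return_indices=True)
        if len(shared) < min_overlap:
            continue
        ra, rb = da.remainder[ia], db.remainder[ib]
        if np.std(ra) == 0 or np.std(rb) == 0:
            logger.info("remainder_correlations: skipping cell %s (zero variance)", cell)
            continue
        rs.append(float(np.corrcoef(ra, rb)[0, 1]))
    if not rs:
        raise ValidationError("remainder_correlations: no qualifying cells")
    rs = np.asarray(rs)
    mean = rs.mean()
    if len(rs) > 1:
        se = rs.std(ddof=1) / np.sqrt(len(rs))
        tcrit = stats.t.ppf(0.975, len(rs) - 1)
        lo, hi = mean - tcrit * se, mean + tcrit * se
    else:
        lo = hi = mean
    return RemainderCorrelationSummary(correlations=rs, mean=float(mean), ci_low=float(lo), ci_high=float(hi))


def cross_cell_year_correlations(paired: dict, min_cells: int = 3) -> np.ndarray:
    """Alternative reading: per-year correlation of remainders across cells.

    For each calendar year present in at least ``min_cells`` paired cells,
    correlate the across-cell vector of insectivore remainders with the
    across-cell vector of insect remainders.
    """
    per_year: dict[int, list[tuple[float, float]]] = {}
    for _, (da, db) in paired.items():
        shared, ia, ib = np.intersect1d(da.years, db.years, return_indices=True)
        for y, a, b in zip(shared, da.remainder[ia], db.remainder[ib]):
            per_year.setdefault(int(y), []).append((a, b))
    out = []
    for y in sorted(per_year):
        pts = np.asarray(per_year[y])
        if len(pts) < min_cells or pts[:, 0].std() == 0 or pts[:, 1].std() == 0:
            continue
        out.append(float(np.corrcoef(pts[:, 0], pts[:, 1])[0, 1]))
    return np.asarray(out)


def decompose_paired_panel(
    panel: pd.DataFrame,
    min_run: int = 10,
    max_zero_frac: float = 0.5,
    span: float = 0.75,
) -> dict:
    """Filter and decompose both taxa of a paired panel, per cell.

    Returns cell id -> (Decomposition insectivore, Decomposition insect)
    for cells where both series pass the longest-run filters.
    """
    out = {}
    for (scale, ix, iy), g in panel.groupby(["scale_m", "ix", "iy"]):
        g = g.sort_values("year")
        run_a = longest_run(g["year"], g["insectivore_value"], min_run, max_zero_frac)
        run_b = longest_run(g["year"], g["insect_value"], min_run, max_zero_frac)
        if run_a is None or run_b is None:
            continue
        out[(int(scale), int(ix), int(iy))] = (
            decompose(*run_a, span=span), decompose(*run_b, span=span)
        )
    return out
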