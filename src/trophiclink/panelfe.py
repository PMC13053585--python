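"""Tier 3 — linearised Gompertz growth models with fixed effects.

The log growth rate of the insectivore index, g_it = log(y_it + 1) -
log(y_{i,t-1} + 1), is regressed on lagged log abundance (density
dependence), contemporaneous and 1-year-lagged insect indices, and
optionally annual temperature and precipitation, after eliminating unit
(and optionally year) fixed effects by demeaning:

    g_it = lambda' log(y_{i,t-1}+1) + b0 Insect_it + b1 Insect_{i,t-1}
           [+ climate] + Site_i [+ Year_t] + e_ir

Four specifications are fitted (M1 unit FE; M2 unit+year FE; M3 = M1 +
climate; M4 = M2 + climate) with CR1 cluster-robust standard errors —
clusters are the units themselves at the 100 km scale and the 100 km
regions at finer scales — and inference uses t with G-1 degrees of
freedom.  Under the Gompertz model the coefficient on lagged log
abundance estimates lambda - 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, ValidationError

logger = logging.getLogger(__name__)

REGRESSORS = ["log_lag_abund", "insect_t", "insect_tm1"]
CLIMATE = ["temp_annual", "precip_annual"]


@dataclass(frozen=True)
class PanelSpec:
    id: str
    year_fe: bool
    climate: bool
    cluster: str = "unit"  # unit | region | twoway


SPECS = {
    "M1": PanelSpec("M1", year_fe=False, climate=False),
    "M2": PanelSpec("M2", year_fe=True, climate=False),
    "M3": PanelSpec("M3", year_fe=False, climate=True),
    "M4": PanelSpec("M4", year_fe=True, climate=True),
}


def build_panel(
    paired: pd.DataFrame,
    max_zero_frac: float = 0.5,
    transform: str = "log1p",
) -> pd.DataFrame:
    """Panel observations (growth rows) from a paired cell-year table.

    Units whose insectivore series is zero more than ``max_zero_frac`` of
    the time are removed (near-absent populations dilute the growth-rate
    signal).  A growth row exists only where two consecutive years have
    both taxa and climate observed.  ``transform="log1p"`` applies the
    log(y+1) transform appropriate for count-scale indices;
    ``transform="identity"`` treats values as already on the log scale
    (used when analysing latent states in recovery experiments).
    """
    if paired.empty:
        raise ValidationError("paired panel table is empty")
    if transform == "log1p":
        f = np.log1p
    elif transform == "identity":
        f = lambda x: x  # noqa: E731
    else:
        raise ValidationError(f"unknown transform {transform!r}")

    rows = []
    n_dropped = 0
    for (scale, ix, iy), g in paired.groupby(["scale_m", "ix", "iy"]):
        g = g.dropna(subset=["insectivore_value", "insect_value"]).sort_values("year")
        if g.empty:
            continue
        if np.mean(g["insectivore_value"] == 0) > max_zero_frac:
            n_dropped += 1
            continue
        yr = g["year"].to_numpy()
        y = f(g["insectivore_value"].to_numpy(dtype=float))
        ins = g["insect_value"].to_numpy(dtype=float)
        temp = g["temp_annual"].to_numpy(dtype=float) if "temp_annual" in g else np.full(len(g), np.nan)
        prec = g["precip_annual"].to_numpy(dtype=float) if "precip_annual" in g else np.full(len(g), np.nan)
        reg_ix = g["region_ix"].iloc[0] if "region_ix" in g else (ix * scale) // 100_000
        reg_iy = g["region_iy"].iloc[0] if "region_iy" in g else (iy * scale) // 100_000
        for t in range(1, len(yr)):
            if yr[t] - yr[t - 1] != 1:
                continue
            if not (np.isfinite(temp[t]) and np.isfinite(prec[t])):
                continue
            rows.append((
                int(scale), int(ix), int(iy), int(reg_ix), int(reg_iy), int(yr[t]),
                y[t] - y[t - 1], y[t - 1], ins[t], ins[t - 1], temp[t], prec[t],
            ))
    if n_dropped:
        logger.info("build_panel: dropped %d units exceeding %.0f%% zeros", n_dropped, 100 * max_zero_frac)
    panel = pd.DataFrame(
        rows,
        columns=["scale_m", "ix", "iy", "region_ix", "region_iy", "year",
                 "growth", "log_lag_abund", "insect_t", "insect_tm1",
                 "temp_annual", "precip_annual"],
    )
    if panel.empty:
        raise ValidationError("build_panel produced no growth rows")
    return panel


def demean(values, *groups, tol: float = 1e-10, max_sweeps: int = 500) -> np.ndarray:
    """Remove group means for one or more grouping factors.

    One factor: subtract each group's mean.  Multiple factors: alternating
    projections — repeatedly subtract each factor's current means until the
    largest absolute change in a sweep falls below ``tol`` (relative to the
    data magnitude, so convergence is scale-invariant).
    """
    if not groups:
        raise ValidationError("demean requires at least one grouping factor")
    x = np.asarray(values, dtype=float).copy()
    codes = [pd.factorize(np.asarray(g))[0] for g in groups]
    if len(codes) == 1:
        c = codes[0]
        means = np.bincount(c, weights=x) / np.bincount(c)
        return x - means[c]
    tol = tol * max(1.0, np.abs(x).max())
    for _ in range(max_sweeps):
        delta = 0.0
        for c in codes:
            means = np.bincount(c, weights=x) / np.bincount(c)
            adj = means[c]
            delta = max(delta, np.abs(adj).max())
            x -= adj
        if delta < tol:
            return x
    raise FitError(f"demeaning did not converge: max residual adjustment {delta:.3e}")


@dataclass
class PanelFit:
    spec: PanelSpec
    coef: pd.Series
    se: pd.Series
    tstat: pd.Series
    pvalue: pd.Series
    vcov: pd.DataFrame
    n_obs: int
    n_units: int
    n_clusters: int
    resid: np.ndarray = field(repr=False, default=None)


def _cluster_vcov(Xd: np.ndarray, resid: np.ndarray, clusters: np.ndarray, K: int) -> np.ndarray:
    """CR1 sandwich: cluster-summed score outer products with small-sample correction."""
    N, k = Xd.shape
    XtX_inv = np.linalg.inv(Xd.T @ Xd)
    codes = pd.factorize(clusters)[0]
    G = codes.max() + 1
    if G < 2:
        raise FitError("cluster-robust covariance requires >= 2 clusters")
    meat = np.zeros((k, k))
    for g in range(G):
        sel = codes == g
        s = Xd[sel].T @ resid[sel]
        meat += np.outer(s, s)
    corr = (G / (G - 1)) * ((N - 1) / (N - K))
    return corr * XtX_inv @ meat @ XtX_inv


def fit_spec(
    panel: pd.DataFrame,
    spec: PanelSpec,
    standardize_insect: bool = True,
) -> PanelFit:
    """Within-estimator OLS for one specification with CR1 clustered SEs.

    Insect covariates are z-scored over the analysis rows by default, so
    coefficients read as the growth response per SD of the insect index.
    ``K`` in the degrees-of-freedom correction counts the absorbed fixed
    effects (units, plus years - 1 when year effects are included) as
    estimated parameters.
    """
    cols = REGRESSORS + (CLIMATE if spec.climate else [])
    data = panel.dropna(subset=cols + ["growth"]).copy()
    if standardize_insect:
        for c in ("insect_t", "insect_tm1"):
            sd = data[c].std(ddof=1)
            if sd > 0:
                data[c] = (data[c] - data[c].mean()) / sd

    unit = data["scale_m"].astype(str) + "_" + data["ix"].astype(str) + "_" + data["iy"].astype(str)
    year = data["year"]
    groups = [unit.to_numpy()] + ([year.to_numpy()] if spec.year_fe else [])

    yd = demean(data["growth"].to_numpy(), *groups)
    Xd = np.column_stack([demean(data[c].to_numpy(), *groups) for c in cols])
    N, k = Xd.shape
    n_units = unit.nunique()
    K = k + n_units + (year.nunique() - 1 if spec.year_fe else 0)

    # rank check on the demeaned regressors
    sv = np.linalg.svd(Xd, compute_uv=False)
    if sv[-1] < max(N, k) * np.finfo(float).eps * sv[0]:
        # name the offending column: smallest residual norm after projecting on others
        norms = []
        for j in range(k):
            others = np.delete(Xd, j, axis=1)
            beta_j = np.linalg.lstsq(others, Xd[:, j], rcond=None)[0]
            norms.append(np.linalg.norm(Xd[:, j] - others @ beta_j))
        raise FitError(
            f"rank-deficient design after demeaning; collinear column: {cols[int(np.argmin(norms))]}"
        )

    beta = np.linalg.lstsq(Xd, yd, rcond=None)[0]
    resid = yd - Xd @ beta

    if spec.cluster == "unit":
        cl = unit.to_numpy()
        V = _cluster_vcov(Xd, resid, cl, K)
        G = unit.nunique()
    elif spec.cluster == "region":
        cl = (data["region_ix"].astype(str) + "_" + data["region_iy"].astype(str)).to_numpy()
        V = _cluster_vcov(Xd, resid, cl, K)
        G = len(np.unique(cl))
    elif spec.cluster == "twoway":
        # inclusion-exclusion combination of unit, region and their intersection
        cl_u = unit.to_numpy()
        cl_r = (data["region_ix"].astype(str) + "_" + data["region_iy"].astype(str)).to_numpy()
        cl_ur = np.char.add(cl_u.astype(str), cl_r)
        V = (
            _cluster_vcov(Xd, resid, cl_u, K)
            + _cluster_vcov(Xd, resid, cl_r, K)
            - _cluster_vcov(Xd, resid, cl_ur, K)
        )
        G = len(np.unique(cl_r))
    else:
        raise ValidationError(f"unknown cluster rule {spec.cluster!r}")

    se = np.sqrt(np.diag(V))
    tstat = beta / se
    pvals = 2 * stats.t.sf(np.abs(tstat), df=G - 1)
    idx = pd.Index(cols)
    return PanelFit(
        spec=spec,
        coef=pd.Series(beta, index=idx),
        se=pd.Series(se, index=idx),
        tstat=pd.Series(tstat, index=idx),
        pvalue=pd.Series(pvals, index=idx),
        vcov=pd.DataFrame(V, index=idx, columns=idx),
        n_obs=N, n_units=n_units, n_clusters=G, resid=resid,
    )


def cluster_rule(scale_m: int) -> str:
    """Units cluster themselves at 100 km; finer scales cluster by region."""
    return "unit" if scale_m == 100_000 else "region"


def run_spec_grid(
    panel: pd.DataFrame,
    scale_m: int,
    standardize_insect: bool = True,
    alpha: float = 0.05,
) -> tuple[dict, pd.DataFrame]:
    """Fit M1-M4 with the scale-appropriate clustering and summarise links.

    Returns (fits by spec id, link summary).  The link summary counts, per
    insect term, how many of the four specifications found a two-sided
    significant effect at ``alpha`` and reports the direction of the mean
    significant coefficient.
    """
    cluster = cluster_rule(scale_m)
    fits: dict[str, PanelFit] = {}
    failures: dict[str, str] = {}
    for sid, base in SPECS.items():
        spec = PanelSpec(sid, base.year_fe, base.climate, cluster)
        try:
            fits[sid] = fit_spec(panel, spec, standardize_insect=standardize_insect)
        except (FitError, ValidationError) as exc:
            failures[sid] = str(exc)
            logger.warning("spec %s failed: %s", sid, exc)
    if not fits:
        raise FitError(f"all four specifications failed: {failures}")

    rows = []
    for term in ("insect_t", "insect_tm1"):
        sig = [f.coef[term] for f in fits.values() if f.pvalue[term] < alpha]
        count = len(sig)
        if count == 0:
            direction = "none"
        else:
            direction = "positive" if np.mean(sig) > 0 else "negative"
        rows.append((scale_m, term, count, direction))
    summary = pd.DataFrame(rows, columns=["scale_m", "term", "n_significant", "direction"])
    return fits, summary
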