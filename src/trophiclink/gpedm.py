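"""Tier 2 — hierarchical Gaussian-process empirical dynamic modelling.

State space is reconstructed by time-delay embedding (delay tau = 1 year,
up to E = 3 lags) of the standardized insectivore index, optionally joined
by insect lags and seasonal weather covariates.  A squared-exponential
kernel with automatic relevance determination (one inverse length scale
phi_d per predictor) is shared across grid cells, with an across-cell
dynamic correlation rho scaling covariance between rows from different
cells — cells share a dynamic map to the degree rho approaches 1.  On the
standardized target the total variance is fixed at 1 and split into a
noise share ve and signal share 1 - ve:

    k(x_i, x_j) = (1 - ve) exp(-sum_d phi_d^2 (x_id - x_jd)^2) * r_ij,
    r_ij = 1 if same cell else rho;   C = K + ve I.

Hyperparameters are MAP estimates (half-normal priors on phi, flat on ve
and rho) and out-of-sample skill is the leave-one-timepoint-out R^2,
computed in closed form from the inverse covariance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .errors import EmbeddingError, FitError

logger = logging.getLogger(__name__)

WEATHER_SETS = ("none", "spring", "summer", "winter", "annual")


@dataclass
class EmbeddingSpec:
    """Which predictors enter the delay matrix."""

    tau: int = 1
    E: int = 3
    include_insect: bool = False
    weather_set: str = "none"          # none | spring | summer | winter | annual
    weather_timing: str = "target_year"  # target_year | lagged
    insect_lag0: bool = False          # optionally allow the contemporaneous insect value

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise EmbeddingError(f"tau must be >= 1, got {self.tau}")
        if not 1 <= self.E <= 3:
            raise EmbeddingError(f"E must be in 1..3, got {self.E}")
        if self.weather_set not in WEATHER_SETS:
            raise EmbeddingError(f"weather_set must be one of {WEATHER_SETS}")
        if self.weather_timing not in ("target_year", "lagged"):
            raise EmbeddingError("weather_timing must be 'target_year' or 'lagged'")


@dataclass
class DelayMatrix:
    X: np.ndarray          # (n, p) standardized predictors
    y: np.ndarray          # (n,) standardized target
    cells: np.ndarray      # (n,) integer cell codes
    years: np.ndarray      # (n,) target calendar years
    columns: list
    cell_ids: list
    y_mean: float
    y_sd: float


def _required_columns(spec: EmbeddingSpec) -> list:
    cols = ["insectivore_value"]
    if spec.include_insect or spec.insect_lag0:
        cols.append("insect_value")
    if spec.weather_set != "none":
        cols += [f"temp_{spec.weather_set}", f"precip_{spec.weather_set}"]
    return cols


def build_embedding(panel: pd.DataFrame, spec: EmbeddingSpec, label: str = "") -> DelayMatrix:
    """Delay matrix over each cell's longest consecutive-year complete run.

    Per cell, the longest run of consecutive calendar years in which every
    required variable is present is retained (ties broken toward the most
    recent run); target years are those with all E lags inside the run.
    Predictor columns and the target are z-scored pooled across cells;
    zero-variance predictor columns are dropped with a log entry.
    """
    req = _required_columns(spec)
    missing = [c for c in req if c not in panel.columns]
    if missing:
        raise EmbeddingError(f"panel lacks required columns {missing} for {label or spec}")
    tau, E = spec.tau, spec.E

    rows, targets, cells, years_out = [], [], [], []
    cell_ids = []
    for code, ((scale, ix, iy), g) in enumerate(panel.groupby(["scale_m", "ix", "iy"])):
        g = g.sort_values("year")
        ok = g[req].notna().all(axis=1).to_numpy()
        yr = g["year"].to_numpy()[ok]
        if len(yr) == 0:
            continue
        sub = g.loc[ok].set_index("year")
        breaks = np.flatnonzero(np.diff(yr) != 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(yr) - 1]])
        lengths = ends - starts + 1
        best = max(range(len(starts)), key=lambda i: (lengths[i], yr[starts[i]]))
        run = yr[starts[best]: ends[best] + 1]
        if len(run) <= E * tau:
            continue
        cell_ids.append((int(scale), int(ix), int(iy)))
        for t in run[E * tau:]:
            row = [sub.at[t - j * tau, "insectivore_value"] for j in range(1, E + 1)]
            if spec.include_insect:
                row += [sub.at[t - j * tau, "insect_value"] for j in range(1, E + 1)]
            if spec.insect_lag0:
                row.append(sub.at[t, "insect_value"])
            if spec.weather_set != "none":
                wt = t if spec.weather_timing == "target_year" else t - tau
                if wt not in sub.index:
                    continue
                row += [sub.at[wt, f"temp_{spec.weather_set}"],
                        sub.at[wt, f"precip_{spec.weather_set}"]]
            rows.append(row)
            targets.append(sub.at[t, "insectivore_value"])
            cells.append(code)
            years_out.append(int(t))

    columns = [f"insectivore_lag{j}" for j in range(1, E + 1)]
    if spec.include_insect:
        columns += [f"insect_lag{j}" for j in range(1, E + 1)]
    if spec.insect_lag0:
        columns.append("insect_lag0")
    if spec.weather_set != "none":
        columns += [f"temp_{spec.weather_set}", f"precip_{spec.weather_set}"]

    if not rows:
        raise EmbeddingError(f"empty delay matrix for {label or spec}")
    X = np.asarray(rows, dtype=float)
    y = np.asarray(targets, dtype=float)
    cells = np.asarray(cells, dtype=int)
    counts = np.bincount(cells)
    if counts.max() < E + 2:
        raise EmbeddingError(
            f"no cell yields >= E+2 = {E + 2} usable rows for {label or spec}"
        )

    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k in zip(columns, keep) if not k]
        logger.info("build_embedding: dropping zero-variance columns %s", dropped)
        X = X[:, keep]
        columns = [c for c, k in zip(columns, keep) if k]
        sd = sd[keep]
    X = (X - X.mean(axis=0)) / sd
    y_mean, y_sd = float(y.mean()), float(y.std(ddof=1))
    if y_sd == 0:
        raise EmbeddingError(f"target has zero variance for {label or spec}")
    y = (y - y_mean) / y_sd
    return DelayMatrix(
        X=X, y=y, cells=cells, years=np.asarray(years_out), columns=columns,
        cell_ids=cell_ids, y_mean=y_mean, y_sd=y_sd,
    )


@dataclass
class GPHyperparams:
    phi: np.ndarray  # inverse length scale per predictor column
    ve: float        # noise share of unit total variance, in (0, 1)
    rho: float       # across-cell dynamic correlation, in [0, 1]


@dataclass
class GPConfig:
    n_starts: int = 5
    prior_scale: float = 1.0
    seed: int = 0
    maxiter: int = 500
    tol: float = 1e-6


@dataclass
class GPFit:
    hyperparams: GPHyperparams
    log_posterior: float
    loo_mean: np.ndarray
    loo_var: np.ndarray
    r2_oos: float
    columns: list


def kernel(xi, xj, cell_i, cell_j, h: GPHyperparams) -> float:
    """Covariance between two embedded states (noise excluded)."""
    xi, xj = np.asarray(xi, float), np.asarray(xj, float)
    if xi.shape != xj.shape or xi.shape[-1] != len(h.phi):
        raise FitError(
            f"kernel dimension mismatch: {xi.shape} vs {xj.shape} with {len(h.phi)} length scales"
        )
    r = 1.0 if cell_i == cell_j else h.rho
    return float((1.0 - h.ve) * np.exp(-np.sum(h.phi ** 2 * (xi - xj) ** 2)) * r)


def _sq_diffs(X: np.ndarray) -> list:
    """Per-dimension squared-difference matrices, cached per delay matrix."""
    return [(X[:, d, None] - X[None, :, d]) ** 2 for d in range(X.shape[1])]


def _gram_parts(sq, same_cell, h: GPHyperparams):
    D = np.zeros_like(sq[0]) if sq else np.zeros(same_cell.shape)
    for d, S in enumerate(sq):
        D += h.phi[d] ** 2 * S
    E = np.exp(-D)
    R = np.where(same_cell, 1.0, h.rho)
    K = (1.0 - h.ve) * E * R
    return E, R, K


def gram_matrix(dm: DelayMatrix, h: GPHyperparams, noise: bool = True) -> np.ndarray:
    """Full covariance of the training targets (optionally + noise diagonal)."""
    sq = _sq_diffs(dm.X)
    same = dm.cells[:, None] == dm.cells[None, :]
    _, _, K = _gram_parts(sq, same, h)
    if noise:
        K = K + h.ve * np.eye(len(dm.y))
    return K


def _chol_with_jitter(C: np.ndarray):
    jitter = 0.0
    while True:
        try:
            return cho_factor(C + jitter * np.eye(len(C)), lower=True), jitter
        except np.linalg.LinAlgError:
            jitter = 1e-8 if jitter == 0.0 else jitter * 10
            if jitter > 1e-4:
                raise FitError("Cholesky failed even with jitter up to 1e-4")


def log_posterior(dm: DelayMatrix, h: GPHyperparams, prior_scale: float = 1.0) -> float:
    """Gaussian log marginal likelihood plus half-normal log-priors on phi."""
    C = gram_matrix(dm, h, noise=True)
    (cf, low), _ = _chol_with_jitter(C)
    alpha = cho_solve((cf, low), dm.y)
    n = len(dm.y)
    ll = -0.5 * dm.y @ alpha - np.sum(np.log(np.diag(cf))) - 0.5 * n * np.log(2 * np.pi)
    prior = -0.5 * np.sum(h.phi ** 2) / prior_scale ** 2
    return float(ll + prior)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _unpack(theta: np.ndarray, p: int) -> GPHyperparams:
    return GPHyperparams(
        phi=np.exp(theta[:p]), ve=float(_sigmoid(theta[p])), rho=float(_sigmoid(theta[p + 1]))
    )


def _neg_logpost_grad(theta, sq, same, y, prior_scale):
    p = len(sq)
    h = _unpack(theta, p)
    E, R, K = _gram_parts(sq, same, h)
    n = len(y)
    C = K + h.ve * np.eye(n)
    (cf, low), _ = _chol_with_jitter(C)
    alpha = cho_solve((cf, low), y)
    Cinv = cho_solve((cf, low), np.eye(n))
    ll = -0.5 * y @ alpha - np.sum(np.log(np.diag(cf))) - 0.5 * n * np.log(2 * np.pi)
    ll += -0.5 * np.sum(h.phi ** 2) / prior_scale ** 2

    grad = np.empty(p + 2)
    W = np.outer(alpha, alpha) - Cinv  # d logL / dC = 0.5 * W
    for d in range(p):
        dC = K * (-2.0 * h.phi[d] ** 2 * sq[d])  # wrt log phi_d
        grad[d] = 0.5 * np.sum(W * dC) - h.phi[d] ** 2 / prior_scale ** 2
    dC_ve = (-E * R + np.eye(n)) * (h.ve * (1.0 - h.ve))
    grad[p] = 0.5 * np.sum(W * dC_ve)
    dC_rho = (1.0 - h.ve) * E * (~same) * (h.rho * (1.0 - h.rho))
    grad[p + 1] = 0.5 * np.sum(W * dC_rho)
    return -ll, -grad


def _start_points(p: int, cfg: GPConfig) -> list:
    rng = np.random.default_rng([int(cfg.seed), 7])
    starts = [np.concatenate([np.log(np.full(p, 0.3)), [np.log(0.25 / 0.75)], [0.0]])]
    for _ in range(max(0, cfg.n_starts - 1)):
        phi = np.abs(rng.normal(0.0, 0.5, p)) + 0.05
        ve = rng.uniform(0.05, 0.6)
        rho = rng.uniform(0.2, 0.95)
        starts.append(np.concatenate([np.log(phi), [np.log(ve / (1 - ve))], [np.log(rho / (1 - rho))]]))
    return starts


def fit(dm: DelayMatrix, config: GPConfig | None = None) -> GPFit:
    """MAP hyperparameters by multi-start quasi-Newton, then closed-form LOO.

    Leave-one-timepoint-out predictions use the Gaussian identity at the
    optimum: with A = C^-1, loo_mean_i = y_i - (Ay)_i / A_ii and
    loo_var_i = 1 / A_ii; r2_oos = 1 - SSE_loo / SST.
    """
    config = config or GPConfig()
    n, p = dm.X.shape
    sq = _sq_diffs(dm.X)
    same = dm.cells[:, None] == dm.cells[None, :]
    if n == 1:
        h = GPHyperparams(phi=np.full(p, 0.3), ve=0.5, rho=0.5)
        return GPFit(h, np.nan, np.zeros(1), np.ones(1), np.nan, dm.columns)

    best, diagnostics = None, []
    for i, x0 in enumerate(_start_points(p, config)):
        try:
            # bounds keep exp/expit transforms away from overflow
            bounds = [(-10.0, 6.0)] * p + [(-9.0, 9.0), (-9.0, 9.0)]
            res = minimize(
                _neg_logpost_grad, x0, args=(sq, same, dm.y, config.prior_scale),
                jac=True, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": config.maxiter, "ftol": config.tol * 1e-3,
                         "gtol": config.tol},
            )
            diagnostics.append(f"start {i}: f={res.fun:.4f} status={res.status}")
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
        except (FitError, FloatingPointError) as exc:  # pragma: no cover - rare
            diagnostics.append(f"start {i}: failed ({exc})")
    if best is None:
        raise FitError("all optimizer starts failed: " + "; ".join(diagnostics))

    h = _unpack(best.x, p)
    C = gram_matrix(dm, h, noise=True)
    (cf, low), _ = _chol_with_jitter(C)
    A = cho_solve((cf, low), np.eye(n))
    Ay = A @ dm.y
    dA = np.diag(A)
    loo_mean = dm.y - Ay / dA
    loo_var = 1.0 / dA
    sst = np.sum((dm.y - dm.y.mean()) ** 2)
    r2 = 1.0 - np.sum((dm.y - loo_mean) ** 2) / sst if sst > 0 else np.nan
    return GPFit(
        hyperparams=h, log_posterior=-float(best.fun), loo_mean=loo_mean,
        loo_var=loo_var, r2_oos=float(r2), columns=dm.columns,
    )


@dataclass
class ComparisonTable:
    """Results of the 10-model suite for one pairing x scale."""

    table: pd.DataFrame
    fits: dict = field(default_factory=dict)


def comparison_suite(
    panel: pd.DataFrame,
    pairing: tuple = ("insectivore", "insects"),
    scale_m: int | None = None,
    gp_config: GPConfig | None = None,
    tau: int = 1,
    E: int = 3,
    weather_timing: str = "target_year",
) -> ComparisonTable:
    """Fit the 10 models: 5 weather sets x insect excluded/included.

    Each of the five head-to-head comparisons contrasts the model without
    insect predictors against the same model with insect lags added; the
    winner is the arm with the higher leave-one-timepoint-out R^2.
    """
    gp_config = gp_config or GPConfig()
    if scale_m is not None:
        panel = panel[panel["scale_m"] == scale_m]
    rows, fits = [], {}
    for ws in WEATHER_SETS:
        for insect in (False, True):
            spec = EmbeddingSpec(
                tau=tau, E=E, include_insect=insect, weather_set=ws,
                weather_timing=weather_timing,
            )
            key = (ws, insect)
            try:
                dm = build_embedding(panel, spec, label=f"{pairing} ws={ws} insect={insect}")
                f = fit(dm, gp_config)
                fits[key] = f
                rows.append((ws, insect, len(dm.y), len(dm.cell_ids), f.r2_oos))
            except EmbeddingError as exc:
                logger.warning("comparison unavailable (%s insect=%s): %s", ws, insect, exc)
                rows.append((ws, insect, 0, 0, np.nan))
    table = pd.DataFrame(
        rows, columns=["weather_set", "insect_included", "n_rows", "n_cells", "r2_oos"]
    )
    # per-comparison winner: insect arm vs matching no-insect arm
    winners = []
    for _, r in table.iterrows():
        if not r["insect_included"]:
            winners.append(np.nan)
            continue
        base = table[(table["weather_set"] == r["weather_set"]) & (~table["insect_included"].astype(bool))]
        b = base["r2_oos"].iloc[0]
        winners.append(bool(r["r2_oos"] > b) if np.isfinite(r["r2_oos"]) and np.isfinite(b) else np.nan)
    table["insect_model_better"] = winners
    if table["r2_oos"].notna().any():
        table["best_model"] = table["r2_oos"] == table["r2_oos"].max()
    else:
        table["best_model"] = False
    table.insert(0, "scale_m", scale_m if scale_m is not None else panel["scale_m"].iloc[0])
    table.insert(0, "pairing", f"{pairing[0]}|{pairing[1]}")
    return ComparisonTable(table=table, fits=fits)
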